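# Methods

## The problem

Cumulative environmental-justice (EJ) screening asks, for every census tract in
a region: how does this tract's combined burden of environmental hazards and
population vulnerability compare with its peers?  No single indicator answers
that — a tract may be unremarkable on ozone yet sit next to a Superfund site in
a linguistically isolated, low-income neighbourhood.  The screening index
implemented here combines 22 indicators into one per-tract score that is easy
to map and to communicate ("higher than 99% of the census tracts in the
county"), the same family of method used by the California and Maryland
state screening tools.

## The scoring model

For each reference geography *G* (all tracts, or one county's tracts) and each
indicator *j*, raw values are rank-transformed to percentiles

    p_ij = (#{k in G : x_kj < x_ij} + 0.5 * #{k : x_kj = x_ij}) / |G|

(midrank convention; values lie strictly inside (0, 1) and ties are handled
symmetrically).  Because only ranks enter, the score is invariant under any
strictly increasing rescaling of a raw column — units, logs, or monotone
calibration changes cannot move a score.

Category scores are unweighted means of the member percentiles:

* **Exposure** E: air-toxics cancer risk, air-toxics respiratory hazard index,
  diesel PM, PM2.5, ozone, traffic proximity-and-volume;
* **Environmental Effects** F: lead paint, proximity to RMP / TSDF / NPL sites
  and major water discharges, watershed failure;
* **Sensitive Populations** S: asthma ER discharges, myocardial-infarction
  discharges, low birth weight;
* **Socioeconomic Factors** C: percent non-White, low-income, less-than-high-
  school, linguistic isolation, under 5, over 64, unemployment.

These combine as

    PollutionBurden        PB = (2/3) E + (1/3) F      (Effects half-weighted)
    PopulationCharacteristics  PC = (S + C) / 2
    ej_raw = PB * PC
    ej_score = percentile of ej_raw within G

The Effects half-weighting reflects that documented effects (site proximity,
old housing stock) contribute less directly to burden than measured ambient
exposures.  Both `ej_raw` (the pre-ranking product) and `ej_score` (the
reported percentile) are emitted.  The multiplicative form means a tract needs
*both* high burden and high vulnerability to score near 1; either factor alone
is insufficient.

### Missing data

Cells are missing, never imputed to zero.  A category mean uses the present
percentiles only, and is itself missing below `min_present` members
(default 1).  If one of the two components of PB or PC is missing, the other
carries full weight and the tract is flagged (`*_renormalized`); screening
practice reports partial scores rather than dropping tracts.  Tracts with a
recorded population of 0 are excluded from every ranking population.  An
indicator column with fewer than two present values in the geography cannot be
ranked and stays missing (a validation warning, not an error).

### Configurable alternatives

* `percentile_method`: `midrank` (default; `hazen` is the same formula under
  average ranks) or `weibull` (`rank/(n+1)`).
* `pollution_burden_mode="pooled"`: instead of combining the two category
  means, pool all Pollution Burden indicators into one mean with each Effects
  indicator half-weighted (the CalEnviroScreen-style pooling).  Not the
  default because the category-mean wording is the stated method.
* `population_characteristics_mode="pooled"`: one grand mean over all 10
  population indicators instead of the mean of the two category means.
* The final product is re-percentiled within each reference geography
  symmetrically; the county score applies the identical pipeline to the county
  subset.

## Exposure kernels

Three indicator families are geometric formulas rather than input columns:

* **Facility proximity** (TSDF, RMP, NPL, major water discharges):
  `sum(1/d_i)` over facilities with great-circle distance `d_i <= 5 km` from
  the tract's representative point — the count of facilities, each weighted by
  inverse distance.  If the buffer is empty the nearest facility contributes
  `1/d_nearest`, so the score is continuous as a site crosses the buffer edge.
  The literal alternative reading "count divided by mean distance" was
  rejected: it is discontinuous when a facility is added at the buffer edge.
* **Traffic proximity and volume**: `sum(AADT_i / d_i)` (vehicles/day per
  metre) over road segments whose closest approach is within 500 m, same
  fallback.
* **Lead paint**: pre-1960 housing units / total units; a tract with no
  housing has a *missing* fraction, not zero.

Numerical choices: haversine distances on a sphere of radius 6371.0088 km
(county-scale work does not warrant a projected CRS); point-to-polyline
closest approach computed in a local equirectangular plane centred on the
tract point (error is O((d/R)^2) — far below 1e-9 relative at the sub-km
ranges where the kernel has weight, which is what the brute-force oracle tests
assert); distance floors of 0.1 km (facilities) and 10 m (roads) cap the
kernel when a hazard is co-located with the evaluation point.  All three
constants are config keys.

The evaluation point per tract is caller-supplied (production tools differ:
centroid vs population-weighted point); the GeoJSON reader falls back to the
polygon's representative point when none is stored.

## Synthetic regions

`generate_region` builds a county group on a square lon/lat grid (default
0.01-degree ≈ 1.1 km cells, origin near 38.94 N) with a planted latent
severity `s in [0,1]` per tract:

* the severity field is *spatially smooth* — a linear gradient plus
  Gaussian-filtered noise, rank-uniformised.  This is a deliberate modelling
  choice: vulnerability clusters in real regions, and because hazard proximity
  is a neighbourhood property, only a spatially autocorrelated field lets
  biased facility siting raise the proximity kernels of the same tracts whose
  demographic indicators are elevated;
* each directly-input indicator is a monotone link of
  `severity_gradient * z + noise_sigma * eps` where `z = Phi^{-1}(s)`:
  logit-normal for proportions, lognormal for concentrations and rates, with
  locations set to plausible magnitudes (PM2.5 around 9 ug/m^3, ozone around
  42 ppb, cancer risk around 30 per million, non-White fraction around 0.35);
* facilities and road midpoints are sited in tracts sampled with probability
  proportional to `exp(siting_bias * s)` and jittered within the cell;
  `siting_bias = 0` reduces to uniform siting.  Kernel indicators are then
  **computed** by the kernel module, never synthesised directly, so the
  generator exercises the production code path;
* defaults: `severity_gradient = 0.8`, `noise_sigma = 0.1`,
  `siting_bias = 2.0`, 51 facilities across four kinds and 40 road segments
  per 100 tracts — enough signal that the planted ordering is recoverable but
  with visible noise.

`bladensburg_like_demo()` is a fixed-seed 150-tract, 3-county region with a
Gaussian severity *peak* planted on one focus tract, emulating a small
overburdened town inside a larger county: the focus tract tops the field, its
neighbourhood is elevated, and hazard siting concentrates around it.

What a green synthetic test does **not** establish: the generator uses square
tracts, a single representative point, independent noise across indicators
beyond the shared severity factor, and no real spatial covariance structure
of pollutant surfaces.  It validates the *mechanics* of the pipeline
(ranking, weighting, kernels, IO), not any empirical claim about a real
region — the published case-study numbers depend on state datasets that are
not distributed with this package.

## Reporting

Tract reports restate score-table cells verbatim (a regeneration test asserts
byte-identical reports and cell-level equality) in the "higher than P% of
census tracts in <geography>" phrasing.  Exported map layers carry a
percentile band label with default edges {0.25, 0.50, 0.75, 0.90}, matching
the 0.75–0.90 and 0.90–1.0 display bands conventional for these tools.  The
bivariate overlay classifies two percentile columns into a 3x3 scheme at
tertile breaks (configurable); the highest class requires both percentiles at
or above the upper break.

## Known limitations

* Percentile evaluation at a single representative point per tract; no
  block-level population weighting of kernels.
* The water-discharge indicator uses the shared facility-proximity kernel;
  RSEI-style toxicity-weighted stream concentrations are inputs, not modelled.
* No uncertainty machinery: the index is deterministic, and rank percentiles
  near the top are unstable under small data changes when tracts are close —
  the tool reports bands for exactly this reason.
* Percent-type indicators must arrive as proportions or be declared via
  `percent_in_hundreds`; the loader cannot guess the convention.
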