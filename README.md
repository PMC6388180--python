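# ejscore

Cumulative environmental-justice (EJ) screening scores for census tracts.

Public-health and planning analysts use screening tools to find communities
that carry both a heavy environmental hazard burden and high population
vulnerability.  `ejscore` implements the tract-level scoring methodology of
the state screening tools (CalEnviroScreen-style): every indicator is
percentile-ranked within a reference geography, averaged into four category
scores, combined into Pollution Burden and Population Characteristics, and the
product is re-ranked to give the final EJ score.

## The score

With within-geography midrank percentiles `p` (ties get the midpoint rank,
values in (0, 1)):

```
E  = mean of the 6 Exposure percentiles         (cancer risk, resp. HI, diesel PM, PM2.5, ozone, traffic)
F  = mean of the 6 Environmental Effects pct.   (lead paint, RMP/TSDF/NPL/water-discharge proximity, watershed)
S  = mean of the 3 Sensitive Populations pct.   (asthma ER, MI discharges, low birth weight)
C  = mean of the 7 Socioeconomic pct.           (non-White, low-income, <HS, ling. isolation, <5, >64, unemployment)

Pollution Burden            PB = (2/3)·E + (1/3)·F
Population Characteristics  PC = (S + C)/2
EJ score                    = percentile of PB·PC within the geography
```

Proximity indicators are inverse-distance kernels computed from hazard
geodata: `Σ 1/dᵢ` over facilities within 5 km (nearest-facility fallback) and
`Σ AADTᵢ/dᵢ` over road segments within 500 m.  Scores can be computed against
the whole region ("statewide") and against a single county's tracts, the two
reference geographies the method reports side by side.

## Worked example

The package ships a seed-fixed synthetic demo region — 150 square-grid tracts
in 3 counties with a planted severity peak on one "focus" tract, hazard
facilities sited preferentially near high-severity tracts, and all 22
indicators generated from the latent severity (see `docs/methods.md`):

```python
from ejscore import bladensburg_like_demo, dual_scores, make_report

fx = bladensburg_like_demo()
county_id = fx.table.county[fx.focus_tract_id]
state, county = dual_scores(fx.table, county_id)
print(make_report(fx.focus_tract_id, state, county, fx.table).to_text())
```

prints (abridged):

```
Tract 24003000085 (county 24003)
[config 359aa7b80ce9]

EJ score (statewide): 0.9967 — higher than 99.7% of census tracts in statewide
  pollution burden 0.9426  population characteristics 0.9967  raw product 0.9395
EJ score (county:24003): 0.9891 — higher than 98.9% of census tracts in county:24003
  pollution burden 0.8998  population characteristics 0.9891  raw product 0.8900

indicator                              raw   statewide pct   county pct
nata_cancer_risk                   57.2101          0.9967       0.9891
nata_resp_hi                      0.853259          0.9967       0.9891
...
```

The focus tract ranks above 99.7% of the 150 tracts region-wide and above
98.9% of its 46 county peers — the planted high-severity locale is recovered
at both reference geographies.  Statewide and county percentiles for the same
raw value differ because each compares against a different ranking population.

The same pipeline from the shell:

```
ejscore simulate --seed 1 --n-tracts 100 --out region/
ejscore score --indicators region/indicators.csv --tracts region/tracts.geojson \
              --out-csv scores.csv --out-geojson ej_layer.geojson
ejscore report --indicators region/indicators.csv --county 24001 --tract <tract_id>
ejscore kernels --tracts region/tracts.geojson --hazards region/hazards.geojson --out kernels.csv
```

`score` writes one row per tract with all intermediate scores plus indicator
percentiles; the GeoJSON layer carries each tract's value and a display band
label (`0.75–0.90`, `0.90–1.0`, ...).  Scoring options (category weights,
percentile convention, kernel radii and distance floors, percent-column
conventions, band edges) are keys of a YAML config passed via `--config`; see
`ejscore.config.ScoringConfig` for every key, default and unit.

## Acceptance script

`scripts/acceptance.py` regenerates a 200-tract synthetic region from the
given seed and runs the complete pipeline — validation, kernel computation,
CSV/GeoJSON round-trip, dual statewide/county scoring, tract report, and map
layer export — writing the result object to `--out`:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
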