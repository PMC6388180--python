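"""Cumulative EJ scoring: percentile ranking, category means, weighted products.

The pipeline for one reference geography (all tracts, or one county's subset):

1. every indicator column is rank-transformed to within-geography percentiles
   in (0, 1) — midrank convention ``(#less + 0.5 * #equal) / n`` by default, so
   scoring is invariant to any strictly increasing rescaling of a raw column;
2. each of the four categories is summarised by the unweighted mean of its
   present percentiles;
3. Pollution Burden = 2/3 * Exposure + 1/3 * Environmental Effects (the
   Effects category is half-weighted); Population Characteristics = mean of
   the Sensitive Populations and Socioeconomic category scores;
4. the raw EJ product = Pollution Burden x Population Characteristics is
   re-ranked within the same geography to give the reported EJ score.

Missing categories renormalise the remaining weight to 1 (and the tract is
flagged) rather than dropping the tract; zero-population tracts never enter a
ranking population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import ScoringConfig
from .indicators import (
    EFFECTS,
    EXPOSURE,
    SENSITIVE,
    SOCIOECONOMIC,
    IndicatorTable,
    build_categories,
)

__all__ = [
    "DegenerateRankingError",
    "PercentileTable",
    "ScoreTable",
    "percentile_rank",
    "category_score",
    "pollution_burden",
    "population_characteristics",
    "compute_scores",
    "dual_scores",
]

STATEWIDE = "statewide"


class DegenerateRankingError(ValueError):
    """Raised when a ranking population has fewer than two present values."""


def percentile_rank(values, method: str = "midrank") -> np.ndarray:
    """Rank values to percentiles in (0, 1); NaN in, NaN out.

    ``midrank`` (default, alias ``hazen``): ``(#strictly-less + 0.5 * #equal) / n``,
    i.e. the average rank shifted by one half and divided by n — symmetric under
    ties and never exactly 0 or 1.  ``weibull``: ``rank / (n + 1)``.
    """
    v = np.asarray(values, dtype=float)
    present = ~np.isnan(v)
    n = int(present.sum())
    if n < 2:
        raise DegenerateRankingError(f"degenerate ranking population (n={n} present values)")
    out = np.full(v.shape, np.nan)
    ranks = rankdata(v[present], method="average")
    if method in ("midrank", "hazen"):
        out[present] = (ranks - 0.5) / n
    elif method == "weibull":
        out[present] = ranks / (n + 1.0)
    else:
        raise ValueError(f"unknown percentile method {method!r}")
    return out


def category_score(percentiles, indicator_ids, min_present: int = 1):
    """Unweighted mean of a category's present percentiles.

    Accepts a single row (Series) or a whole PercentileTable frame.  Returns
    NaN where fewer than *min_present* member percentiles are present.
    """
    if isinstance(percentiles, pd.Series):
        sub = percentiles.reindex(list(indicator_ids)).astype(float)
        if sub.notna().sum() < min_present:
            return float("nan")
        return float(sub.mean())
    cols = [c for c in indicator_ids if c in percentiles.columns]
    sub = percentiles.reindex(columns=list(indicator_ids)).astype(float) if cols else None
    if sub is None:
        return pd.Series(np.nan, index=percentiles.index)
    means = sub.mean(axis=1, skipna=True)
    means[sub.notna().sum(axis=1) < min_present] = np.nan
    return means


def _weighted_pair(a, b, wa_num: int, wb_num: int, denom: int):
    """(wa*a + wb*b)/denom elementwise, renormalising when one side is missing.

    Returns (values, renormalised-mask).  Written with integer numerators over a
    common denominator so the corner cases reproduce the stated weights exactly
    in floating point.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    both = ~np.isnan(a) & ~np.isnan(b)
    only_a = ~np.isnan(a) & np.isnan(b)
    only_b = np.isnan(a) & ~np.isnan(b)
    out = np.full(np.broadcast(a, b).shape, np.nan)
    out[both] = (wa_num * a[both] + wb_num * b[both]) / denom
    out[only_a] = a[only_a]
    out[only_b] = b[only_b]
    return out, only_a | only_b


def pollution_burden(exposure_score, effects_score, config: ScoringConfig | None = None):
    """Weighted mean of the Exposure and Environmental Effects category scores.

    Defaults to 2/3 Exposure + 1/3 Effects.  If one category is missing the
    other carries full weight (renormalised, flagged by the caller); both
    missing yields NaN.
    """
    config = config or ScoringConfig()
    we, wf = config.exposure_weight, config.effects_weight
    denom = np.lcm(we.denominator, wf.denominator)
    values, renorm = _weighted_pair(
        exposure_score, effects_score, we.numerator * denom // we.denominator,
        wf.numerator * denom // wf.denominator, denom,
    )
    if np.ndim(exposure_score) == 0 and np.ndim(effects_score) == 0:
        return float(values)
    return values, renorm


def population_characteristics(senspop_score, ses_score):
    """Equal-weight mean of the Sensitive Populations and Socioeconomic scores."""
    values, renorm = _weighted_pair(senspop_score, ses_score, 1, 1, 2)
    if np.ndim(senspop_score) == 0 and np.ndim(ses_score) == 0:
        return float(values)
    return values, renorm


@dataclass
class PercentileTable:
    """Within-geography indicator percentiles, same shape as the raw table."""

    data: pd.DataFrame
    reference_geography: str

    def row(self, tract_id: str) -> pd.Series:
        return self.data.loc[tract_id]


@dataclass
class ScoreTable:
    """Per-tract category scores, Pollution Burden, Population Characteristics,
    the raw EJ product, and the percentile-ranked EJ score.

    ``scores`` columns: exposure_score, effects_score, senspop_score, ses_score,
    pollution_burden, population_characteristics, ej_raw, ej_score, flags.
    """

    scores: pd.DataFrame
    percentiles: PercentileTable
    reference_geography: str

    def row(self, tract_id: str) -> pd.Series:
        return self.scores.loc[tract_id]


def _normalize_geography(geography) -> tuple[str, str | None]:
    if geography in (None, STATEWIDE):
        return STATEWIDE, None
    if isinstance(geography, str):
        if geography.startswith("county:"):
            return "county", geography.split(":", 1)[1]
        raise ValueError(f"unknown geography {geography!r}")
    kind, county_id = geography
    if kind != "county":
        raise ValueError(f"unknown geography kind {kind!r}")
    return "county", str(county_id)


def compute_scores(
    table: IndicatorTable,
    config: ScoringConfig | None = None,
    geography="statewide",
) -> ScoreTable:
    """Run the full scoring pipeline within one reference geography.

    *geography* is ``"statewide"`` (rank against every scoreable tract) or
    ``("county", id)`` / ``"county:ID"`` (rank only against that county's
    tracts, the county-reference score of the methodology).  Deterministic
    given inputs.
    """
    config = config or ScoringConfig()
    kind, county_id = _normalize_geography(geography)
    mask = table.scoreable
    if kind == "county":
        if table.county is None:
            raise ValueError("table has no county_id column; county geography unavailable")
        if county_id not in set(table.county.dropna()):
            raise ValueError(f"unknown county_id {county_id!r}")
        mask = mask & (table.county == county_id)
        geo_name = f"county:{county_id}"
    else:
        geo_name = STATEWIDE
    sub = table.data.loc[mask, table.indicator_columns].astype(float)
    if len(sub) < 2:
        raise DegenerateRankingError(f"fewer than 2 scoreable tracts in geography {geo_name!r}")

    pct = pd.DataFrame(index=sub.index, dtype=float)
    for col in sub.columns:
        if sub[col].notna().sum() < 2:
            pct[col] = np.nan  # unrankable column: left missing, flagged by validate()
        else:
            pct[col] = percentile_rank(sub[col].to_numpy(), config.percentile_method)

    cats = build_categories(table.schema, config)
    mp = config.min_present
    exposure = category_score(pct, cats[EXPOSURE].indicator_ids, mp)
    effects = category_score(pct, cats[EFFECTS].indicator_ids, mp)
    senspop = category_score(pct, cats[SENSITIVE].indicator_ids, mp)
    ses = category_score(pct, cats[SOCIOECONOMIC].indicator_ids, mp)

    flags = pd.Series("", index=sub.index, dtype=object)
    if config.pollution_burden_mode == "pooled":
        # CalEnviroScreen-style pooling: every Effects indicator half-weighted
        # inside one grand mean over Pollution Burden indicators.
        w = pd.Series(0.0, index=pct.columns)
        w[w.index.intersection(cats[EXPOSURE].indicator_ids)] = 1.0
        w[w.index.intersection(cats[EFFECTS].indicator_ids)] = 0.5
        weights = pct.notna().mul(w, axis=1)
        pb = pct.mul(w, axis=1).sum(axis=1, skipna=True) / weights.sum(axis=1).replace(0.0, np.nan)
        pb = pb.to_numpy()
    else:
        pb, renorm = pollution_burden(exposure.to_numpy(), effects.to_numpy(), config)
        flags[renorm] = flags[renorm] + "pollution_burden_renormalized;"
    if config.population_characteristics_mode == "pooled":
        pooled_ids = cats[SENSITIVE].indicator_ids + cats[SOCIOECONOMIC].indicator_ids
        pc = category_score(pct, pooled_ids, mp).to_numpy()
    else:
        pc, renorm = population_characteristics(senspop.to_numpy(), ses.to_numpy())
        flags[renorm] = flags[renorm] + "population_characteristics_renormalized;"

    ej_raw = pb * pc
    ej_score = np.full(ej_raw.shape, np.nan)
    present = ~np.isnan(ej_raw)
    if present.sum() >= 2:
        ej_score[present] = percentile_rank(ej_raw[present], config.percentile_method)

    scores = pd.DataFrame(
        {
            "exposure_score": exposure,
            "effects_score": effects,
            "senspop_score": senspop,
            "ses_score": ses,
            "pollution_burden": pb,
            "population_characteristics": pc,
            "ej_raw": ej_raw,
            "ej_score": ej_score,
            "flags": flags,
        },
        index=sub.index,
    )
    return ScoreTable(scores, PercentileTable(pct, geo_name), geo_name)


def dual_scores(
    table: IndicatorTable,
    county_id: str,
    config: ScoringConfig | None = None,
) -> tuple[ScoreTable, ScoreTable]:
    """Statewide and county-reference scores for the same table.

    A county tract appears in both outputs, generally with different
    percentiles: the county score compares it only to its county peers, the
    statewide score to every tract.
    """
    if table.county is None:
        raise ValueError("table has no county_id column")
    if county_id not in set(table.county.dropna()):
        raise ValueError(f"unknown county_id {county_id!r}")
    state = compute_scores(table, config, STATEWIDE)
    county = compute_scores(table, config, ("county", county_id))
    return state, county
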