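"""Indicator schema and per-tract indicator tables.

The screening method scores census tracts on 22 indicators organised in four
categories: Pollution Burden is built from *Exposure* (ambient and air-toxics
concentrations, traffic) and *Environmental Effects* (proximity to hazardous
facilities, lead paint, watershed failure); Population Characteristics from
*Sensitive Populations* (health outcomes) and *Socioeconomic Factors*
(demographics).  All indicators point the same way: a larger value means a
worse condition, so percentile ranks are directly comparable across columns.

Percent-type indicators are stored internally as proportions in ``[0, 1]``;
the loader converts declared 0-100 columns once on ingest so no downstream
code ever guesses the convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CategorySpec",
    "IndicatorDef",
    "IndicatorTable",
    "Finding",
    "default_schema",
    "build_categories",
    "load_indicator_table",
    "write_indicator_table",
    "validate",
    "EXPOSURE",
    "EFFECTS",
    "SENSITIVE",
    "SOCIOECONOMIC",
    "KERNEL_INDICATORS",
]

EXPOSURE = "exposure"
EFFECTS = "environmental_effects"
SENSITIVE = "sensitive_populations"
SOCIOECONOMIC = "socioeconomic"
CATEGORIES = (EXPOSURE, EFFECTS, SENSITIVE, SOCIOECONOMIC)

#: indicators whose values are computed from hazard geometry rather than read
#: from an input column
KERNEL_INDICATORS = frozenset(
    {
        "proximity_tsdf",
        "proximity_rmp",
        "proximity_npl",
        "proximity_water_discharge",
        "traffic",
        "lead_paint",
    }
)

TRACT_ID = "tract_id"
COUNTY_ID = "county_id"
POPULATION = "population"
RESERVED_COLUMNS = (TRACT_ID, COUNTY_ID, POPULATION)


@dataclass(frozen=True)
class IndicatorDef:
    """One indicator: identifier, category membership, units, provenance."""

    id: str
    category: str
    units: str
    source: str = "input_column"  # or "computed_kernel"
    percent: bool = False  # stored as a proportion in [0, 1]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.id!r}")
        if self.source not in ("input_column", "computed_kernel"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.source == "computed_kernel" and self.id not in KERNEL_INDICATORS:
            raise ValueError(f"{self.id!r} cannot be kernel-computed")


@dataclass(frozen=True)
class CategorySpec:
    """A category of indicators and its weight within its parent score."""

    name: str
    weight_in_parent: Fraction
    indicator_ids: tuple[str, ...]


def default_schema() -> list[IndicatorDef]:
    """The 22 default indicators, by category block.

    Exposure (6): air-toxics lifetime cancer risk, air-toxics respiratory
    hazard index, diesel PM, PM2.5, ozone, traffic proximity-and-volume.
    Environmental Effects (6): lead paint, and proximity to RMP / TSDF / NPL
    sites and major direct water discharges, watershed failure.
    Sensitive Populations (3): asthma ER discharges, myocardial infarction
    discharges, low-birth-weight infants.
    Socioeconomic Factors (7): percent non-White, low-income, less-than-high-
    school education, linguistic isolation, under 5, over 64, unemployment.
    """
    D = IndicatorDef
    return [
        # Pollution Burden: Exposure
        D("nata_cancer_risk", EXPOSURE, "lifetime cancer risk per million"),
        D("nata_resp_hi", EXPOSURE, "respiratory hazard index (ratio)"),
        D("nata_dpm", EXPOSURE, "diesel PM, ug/m^3"),
        D("pm25", EXPOSURE, "PM2.5, ug/m^3"),
        D("ozone", EXPOSURE, "summer seasonal 8-h max ozone, ppb"),
        D("traffic", EXPOSURE, "AADT / distance, vehicles/day per m", source="computed_kernel"),
        # Pollution Burden: Environmental Effects
        D("lead_paint", EFFECTS, "fraction of housing pre-1960", source="computed_kernel", percent=True),
        D("proximity_rmp", EFFECTS, "sum 1/d over RMP sites within 5 km, 1/km", source="computed_kernel"),
        D("proximity_tsdf", EFFECTS, "sum 1/d over TSDFs within 5 km, 1/km", source="computed_kernel"),
        D("proximity_npl", EFFECTS, "sum 1/d over NPL sites within 5 km, 1/km", source="computed_kernel"),
        D("proximity_water_discharge", EFFECTS, "sum 1/d over major discharges, 1/km", source="computed_kernel"),
        D("watershed_failure", EFFECTS, "fraction of tract watershed failing N/P", percent=True),
        # Population Characteristics: Sensitive Populations
        D("asthma_er_discharges", SENSITIVE, "discharges per 10,000"),
        D("mi_discharges", SENSITIVE, "discharges per 10,000"),
        D("low_birth_weight", SENSITIVE, "fraction of births < 5.5 lb", percent=True),
        # Population Characteristics: Socioeconomic Factors
        D("pct_nonwhite", SOCIOECONOMIC, "fraction non-White", percent=True),
        D("pct_low_income", SOCIOECONOMIC, "fraction below 2x poverty", percent=True),
        D("pct_less_hs", SOCIOECONOMIC, "fraction 25+ without HS diploma", percent=True),
        D("pct_linguistic_isolation", SOCIOECONOMIC, "fraction linguistically isolated households", percent=True),
        D("pct_under_5", SOCIOECONOMIC, "fraction under age 5", percent=True),
        D("pct_over_64", SOCIOECONOMIC, "fraction over age 64", percent=True),
        D("pct_unemployed", SOCIOECONOMIC, "fraction of labour force unemployed", percent=True),
    ]


def build_categories(schema: list[IndicatorDef] | None = None, config=None) -> dict[str, CategorySpec]:
    """Group a schema into the four weighted category specs.

    Exposure and Effects weights come from *config* (defaults 2/3, 1/3) and must
    sum to 1; the two population categories are equally weighted.
    """
    from .config import ScoringConfig

    schema = default_schema() if schema is None else schema
    config = config or ScoringConfig()
    ids: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    seen: set[str] = set()
    for d in schema:
        if d.id in seen:
            raise ValueError(f"duplicate indicator id {d.id!r}")
        seen.add(d.id)
        ids[d.category].append(d.id)
    weights = {
        EXPOSURE: config.exposure_weight,
        EFFECTS: config.effects_weight,
        SENSITIVE: Fraction(1, 2),
        SOCIOECONOMIC: Fraction(1, 2),
    }
    return {c: CategorySpec(c, weights[c], tuple(ids[c])) for c in CATEGORIES}


@dataclass
class IndicatorTable:
    """Per-tract raw indicator values plus reference-geography metadata.

    ``data`` is indexed by tract_id (opaque string; 11-digit FIPS recommended)
    and holds one float column per indicator, NaN marking a missing cell.
    Unknown input columns are preserved in ``data`` and listed in
    ``passthrough``; they never enter a score.  A tract with population 0 is
    excluded from percentile ranking.
    """

    data: pd.DataFrame
    schema: list[IndicatorDef] = field(default_factory=default_schema)
    county: pd.Series | None = None
    population: pd.Series | None = None
    passthrough: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate tract_id: {dupes}")

    @property
    def indicator_columns(self) -> list[str]:
        known = {d.id for d in self.schema}
        return [c for c in self.data.columns if c in known]

    @property
    def scoreable(self) -> pd.Series:
        """Boolean mask of tracts eligible for ranking (population > 0 or unknown)."""
        if self.population is None:
            return pd.Series(True, index=self.data.index)
        return (self.population.isna() | (self.population > 0)).reindex(self.data.index, fill_value=True)

    def tract_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning" | "info"
    tract_id: str | None
    indicator_id: str | None
    message: str


def load_indicator_table(
    path: str | Path,
    schema: list[IndicatorDef] | None = None,
    percent_in_hundreds: tuple[str, ...] = (),
) -> IndicatorTable:
    """Load and validate a per-tract indicator CSV.

    The file must have a header with ``tract_id`` and at least one known
    indicator column.  Optional ``county_id`` and ``population`` columns supply
    the reference geography and the zero-population exclusion flag.  Columns
    named in *percent_in_hundreds* are declared on the 0-100 scale and divided
    by 100 on ingest.  Unknown columns are carried through untouched.
    """
    path = Path(path)
    schema = default_schema() if schema is None else schema
    known = {d.id for d in schema}
    raw = pd.read_csv(path, dtype={TRACT_ID: str, COUNTY_ID: str}, float_precision="round_trip")
    if TRACT_ID not in raw.columns:
        raise ValueError(f"{path}: missing required column {TRACT_ID!r}")
    indicator_cols = [c for c in raw.columns if c in known]
    if not indicator_cols:
        raise ValueError(f"{path}: no known indicator columns in header")
    dup = raw[TRACT_ID][raw[TRACT_ID].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate tract_id {dup}")

    raw = raw.set_index(TRACT_ID)
    numeric_cols = indicator_cols + ([POPULATION] if POPULATION in raw.columns else [])
    for col in numeric_cols:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna() & (raw[col].astype(str).str.strip() != "")
        if bad.any():
            tid = raw.index[bad][0]
            raise ValueError(f"{path}: non-numeric value {raw.loc[tid, col]!r} in column {col!r}, tract {tid}")
        raw[col] = coerced.astype(float)

    for col in percent_in_hundreds:
        if col in indicator_cols:
            raw[col] = raw[col] / 100.0

    county = raw.pop(COUNTY_ID) if COUNTY_ID in raw.columns else None
    population = raw.pop(POPULATION) if POPULATION in raw.columns else None
    passthrough = [c for c in raw.columns if c not in known]
    return IndicatorTable(raw, schema, county, population, passthrough)


def write_indicator_table(table: IndicatorTable, path: str | Path) -> Path:
    """Write back to CSV; finite values round-trip bit-exactly (repr-based floats)."""
    out = table.data.copy()
    if table.population is not None:
        out.insert(0, POPULATION, table.population)
    if table.county is not None:
        out.insert(0, COUNTY_ID, table.county)
    path = Path(path)
    out.to_csv(path, index_label=TRACT_ID)
    return path


def validate(table: IndicatorTable, schema: list[IndicatorDef] | None = None) -> list[Finding]:
    """Domain checks; returns findings instead of raising.

    error: negative value for a nonnegative indicator; proportion outside [0,1].
    warning: a tract with every indicator of some category missing ("category
    unscorable"); an indicator column with < 2 present values (unrankable).
    info: zero-population tracts excluded from ranking.
    """
    schema = schema or table.schema
    defs = {d.id: d for d in schema}
    cats = build_categories(schema)
    findings: list[Finding] = []
    for col in table.indicator_columns:
        series = table.data[col]
        neg = series < 0
        for tid in table.data.index[neg.fillna(False)]:
            findings.append(Finding("error", tid, col, f"negative value {series[tid]!r}"))
        if defs[col].percent:
            out = (series < 0) | (series > 1)
            for tid in table.data.index[out.fillna(False)]:
                findings.append(
                    Finding("error", tid, col, f"proportion {series[tid]!r} outside [0, 1]")
                )
        if series.notna().sum() < 2:
            findings.append(Finding("warning", None, col, "fewer than 2 present values; unrankable"))
    present_cols = set(table.indicator_columns)
    for cat in cats.values():
        cols = [c for c in cat.indicator_ids if c in present_cols]
        if not cols:
            findings.append(Finding("warning", None, None, f"category {cat.name!r} has no indicator columns"))
            continue
        all_missing = table.data[cols].isna().all(axis=1)
        for tid in table.data.index[all_missing]:
            findings.append(Finding("warning", tid, None, f"category {cat.name!r} unscorable"))
    if table.population is not None:
        for tid in table.data.index[(table.population == 0).reindex(table.data.index, fill_value=False)]:
            findings.append(Finding("info", tid, None, "zero population; excluded from ranking"))
    return findings
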