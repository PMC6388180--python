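"""Tract reports, choropleth layer export, and bivariate overlays.

Reports restate score-table cells verbatim (the consistency contract: every
number printed is findable in the underlying tables) in the familiar
"higher than P% of census tracts in <geography>" phrasing.  Map layers are
GeoJSON FeatureCollections whose features carry the value and a percentile
band label; display bands default to 0-0.25 / 0.25-0.50 / 0.50-0.75 /
0.75-0.90 / 0.90-1.0.
"""

from __future__ import annotations

import difflib
import json
import warnings
from bisect import bisect_left
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .config import ScoringConfig
from .geojson import read_feature_collection, write_feature_collection
from .indicators import IndicatorTable
from .scoring import ScoreTable

__all__ = [
    "TractReport",
    "OverlayLayer",
    "band_label",
    "make_report",
    "export_layer",
    "load_layer_values",
    "overlay",
]


def _fmt_edge(x: float) -> str:
    if x == 0:
        return "0"
    if x == 1:
        return "1.0"
    return f"{x:.2f}"


def band_label(value: float, bands: tuple[float, ...] = (0.25, 0.5, 0.75, 0.9)) -> str:
    """Display band for a percentile, e.g. 0.83 -> '0.75-0.90' (en dash)."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"percentile {value!r} outside [0, 1]")
    edges = [0.0, *bands, 1.0]
    i = bisect_left(list(bands), value)
    return f"{_fmt_edge(edges[i])}–{_fmt_edge(edges[i + 1])}"


SCORE_FIELDS = (
    "exposure_score",
    "effects_score",
    "senspop_score",
    "ses_score",
    "pollution_burden",
    "population_characteristics",
    "ej_raw",
    "ej_score",
)


@dataclass
class TractReport:
    """Everything the tool knows about one tract, at both reference geographies."""

    tract_id: str
    county_id: str | None
    indicators: pd.DataFrame  # columns: raw, statewide_pct, county_pct
    statewide: dict[str, float]  # the SCORE_FIELDS of the statewide ScoreTable row
    county: dict[str, float]
    statewide_geography: str
    county_geography: str
    config_digest: str

    def to_dict(self) -> dict:
        return {
            "tract_id": self.tract_id,
            "county_id": self.county_id,
            "indicators": {
                ind: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for ind, row in self.indicators.iterrows()
            },
            "statewide": self.statewide,
            "county": self.county,
            "config_digest": self.config_digest,
        }

    def to_text(self) -> str:
        lines = [
            f"Tract {self.tract_id} (county {self.county_id})",
            f"[config {self.config_digest}]",
            "",
        ]
        for geo, scores in ((self.statewide_geography, self.statewide), (self.county_geography, self.county)):
            ej = scores["ej_score"]
            if ej is None or (isinstance(ej, float) and np.isnan(ej)):
                lines.append(f"EJ score ({geo}): not scoreable")
                continue
            lines.append(
                f"EJ score ({geo}): {ej:.4f} — higher than {100 * ej:.1f}% of census tracts in {geo}"
            )
            lines.append(
                "  pollution burden {pollution_burden:.4f}  population characteristics "
                "{population_characteristics:.4f}  raw product {ej_raw:.4f}".format(**scores)
            )
        lines.append("")
        lines.append(f"{'indicator':<28}{'raw':>14}{'statewide pct':>16}{'county pct':>13}")
        for ind, row in self.indicators.iterrows():
            raw = "missing" if pd.isna(row["raw"]) else f"{row['raw']:.6g}"
            sp = "—" if pd.isna(row["statewide_pct"]) else f"{row['statewide_pct']:.4f}"
            cp = "—" if pd.isna(row["county_pct"]) else f"{row['county_pct']:.4f}"
            lines.append(f"{ind:<28}{raw:>14}{sp:>16}{cp:>13}")
        return "\n".join(lines) + "\n"


def make_report(
    tract_id: str,
    statewide: ScoreTable,
    county: ScoreTable,
    table: IndicatorTable,
    config: ScoringConfig | None = None,
) -> TractReport:
    """Assemble a per-tract report from already-computed dual score tables."""
    config = config or ScoringConfig()
    for st in (statewide, county):
        if tract_id not in st.scores.index:
            close = difflib.get_close_matches(tract_id, list(st.scores.index), n=3, cutoff=0.0)
            raise KeyError(
                f"tract {tract_id!r} not in {st.reference_geography} scores; closest IDs: {close}"
            )
    cols = table.indicator_columns
    ind = pd.DataFrame(
        {
            "raw": table.data.loc[tract_id, cols].astype(float),
            "statewide_pct": statewide.percentiles.row(tract_id).reindex(cols),
            "county_pct": county.percentiles.row(tract_id).reindex(cols),
        }
    )
    def _scores(st: ScoreTable) -> dict[str, float]:
        row = st.row(tract_id)
        return {k: (None if pd.isna(row[k]) else float(row[k])) for k in SCORE_FIELDS}

    county_id = None if table.county is None else table.county.get(tract_id)
    return TractReport(
        tract_id,
        county_id,
        ind,
        _scores(statewide),
        _scores(county),
        statewide.reference_geography,
        county.reference_geography,
        config.digest(),
    )


def export_layer(
    values: pd.Series,
    geometries: dict[str, Polygon],
    path: str | Path,
    bands: tuple[float, ...] = (0.25, 0.5, 0.75, 0.9),
    column: str = "value",
) -> Path:
    """Write one score/percentile column as a GeoJSON choropleth layer.

    Each feature carries ``tract_id``, the value under *column*, and a
    ``band`` label when the value is a percentile in [0, 1].  Tracts without
    geometry are skipped with a warning.
    """
    features = []
    for tract_id, value in values.items():
        geom = geometries.get(tract_id)
        if geom is None:
            warnings.warn(f"no geometry for tract {tract_id!r}; feature skipped")
            continue
        props = {"tract_id": tract_id, column: None if pd.isna(value) else float(value)}
        if props[column] is not None and 0.0 <= value <= 1.0:
            props["band"] = band_label(float(value), bands)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [list(map(list, geom.exterior.coords))]},
                "properties": props,
            }
        )
    return write_feature_collection(features, path)


def load_layer_values(path: str | Path, column: str = "value") -> dict[str, float]:
    """Re-read an exported layer as a tract_id -> value mapping."""
    return {
        f["properties"]["tract_id"]: f["properties"][column]
        for f in read_feature_collection(path)
    }


@dataclass
class OverlayLayer:
    """3x3 bivariate classification of two percentile columns."""

    data: pd.DataFrame  # columns: pct_a, pct_b, class_a, class_b, label
    breaks: tuple[float, float]

    def counts(self) -> pd.Series:
        return self.data["label"].value_counts()


def _tri_class(p: pd.Series, breaks: tuple[float, float]) -> pd.Series:
    lo, hi = breaks
    return pd.Series(
        np.where(p >= hi, "high", np.where(p >= lo, "mid", "low")), index=p.index
    )


def overlay(
    percentile_a: pd.Series,
    percentile_b: pd.Series,
    breaks: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0),
) -> OverlayLayer:
    """Classify tract pairs of percentiles into a 3x3 bivariate scheme.

    The highest class requires both percentiles at or above the upper break.
    Inputs must be percentile-valued (within [0, 1]).
    """
    a = percentile_a.astype(float)
    b = percentile_b.astype(float).reindex(a.index)
    for name, col in (("A", a), ("B", b)):
        bad = col.dropna()
        if len(bad) and ((bad < 0) | (bad > 1)).any():
            raise ValueError(f"column {name} is not percentile-valued (outside [0, 1])")
    ca, cb = _tri_class(a, breaks), _tri_class(b, breaks)
    df = pd.DataFrame(
        {"pct_a": a, "pct_b": b, "class_a": ca, "class_b": cb,
         "label": ca.str.cat(cb, sep="/")}
    )
    df.loc[a.isna() | b.isna(), ["class_a", "class_b", "label"]] = np.nan
    return OverlayLayer(df, breaks)
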