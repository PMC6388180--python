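"""Scoring configuration: category weights, percentile conventions, kernel radii.

All tunables that alter a score live here so that a run can be reproduced from a
single YAML file.  Weights are exact rationals (:class:`fractions.Fraction`) so the
printed 2/3 and 1/3 pollution-burden weights survive serialisation round-trips.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, replace
from fractions import Fraction
from pathlib import Path

import yaml

__all__ = ["ScoringConfig", "load_config"]


@dataclass(frozen=True)
class ScoringConfig:
    """Every knob of the scoring pipeline, with screening-tool defaults.

    Parameters
    ----------
    exposure_weight, effects_weight:
        Weights of the Exposure and Environmental Effects category means inside
        Pollution Burden.  Defaults 2/3 and 1/3 (Effects is half-weighted because
        documented effects contribute less to burden than measured exposures).
        Must sum to 1.
    percentile_method:
        ``"midrank"`` (default; ``(#less + 0.5*#equal)/n``, a.k.a. Hazen plotting
        position under average ranks) or ``"weibull"`` (``rank/(n+1)``).
    min_present:
        Minimum number of non-missing indicator percentiles required before a
        category mean is reported; below it the category is missing.
    pollution_burden_mode / population_characteristics_mode:
        ``"category"`` (default): combine the *category means* (Effects
        half-weighted; Sensitive Populations and Socioeconomic equally weighted).
        ``"pooled"``: pool the member indicators directly (each Effects indicator
        half-weighted; Population Characteristics as one grand mean).
    radius_km / radius_m:
        Facility-proximity buffer (km) and traffic buffer (m).
    min_distance_km / min_distance_m:
        Distance floors so a hazard co-located with the tract point cannot
        produce 1/0.
    percentile_bands:
        Interior edges of the display bands used on exported map layers.
    overlay_breaks:
        The two breaks of the 3x3 bivariate overlay classification (tertiles).
    """

    exposure_weight: Fraction = Fraction(2, 3)
    effects_weight: Fraction = Fraction(1, 3)
    percentile_method: str = "midrank"
    min_present: int = 1
    pollution_burden_mode: str = "category"
    population_characteristics_mode: str = "category"
    radius_km: float = 5.0
    radius_m: float = 500.0
    min_distance_km: float = 0.1
    min_distance_m: float = 10.0
    percentile_bands: tuple[float, ...] = (0.25, 0.5, 0.75, 0.9)
    overlay_breaks: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    percent_in_hundreds: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.exposure_weight + self.effects_weight != 1:
            raise ValueError(
                "pollution-burden weights must sum to 1, got "
                f"{self.exposure_weight} + {self.effects_weight}"
            )
        if self.percentile_method not in ("midrank", "hazen", "weibull"):
            raise ValueError(f"unknown percentile method {self.percentile_method!r}")
        if self.pollution_burden_mode not in ("category", "pooled"):
            raise ValueError(f"unknown pollution_burden_mode {self.pollution_burden_mode!r}")
        if self.population_characteristics_mode not in ("category", "pooled"):
            raise ValueError(
                f"unknown population_characteristics_mode {self.population_characteristics_mode!r}"
            )
        if self.min_present < 1:
            raise ValueError("min_present must be >= 1")
        for name in ("radius_km", "radius_m", "min_distance_km", "min_distance_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, Fraction):
                v = str(v)
            elif isinstance(v, tuple):
                v = list(v)
            d[f.name] = v
        return d

    def digest(self) -> str:
        """Stable short hash identifying this configuration in reports."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def with_(self, **kwargs) -> "ScoringConfig":
        for key in ("exposure_weight", "effects_weight"):
            if key in kwargs and not isinstance(kwargs[key], Fraction):
                kwargs[key] = Fraction(kwargs[key])
        return replace(self, **kwargs)


def load_config(path: str | Path) -> ScoringConfig:
    """Read a YAML key-value config file; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(ScoringConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("exposure_weight", "effects_weight"):
        if key in raw:
            raw[key] = Fraction(str(raw[key]))
    for key in ("percentile_bands", "overlay_breaks", "percent_in_hundreds"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return ScoringConfig(**raw)
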