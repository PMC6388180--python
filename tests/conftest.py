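import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ejscore import IndicatorTable, RegionConfig, bladensburg_like_demo, default_schema, generate_region

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")

INDICATOR_IDS = [d.id for d in default_schema()]


def random_table(seed: int, n_tracts: int = 200, n_counties: int = 2) -> IndicatorTable:
    """A random raw table over the default schema (ranks are all that matter)."""
    rng = np.random.default_rng(seed)
    index = pd.Index([f"24{i:09d}" for i in range(n_tracts)], name="tract_id")
    data = pd.DataFrame(
        rng.standard_normal((n_tracts, len(INDICATOR_IDS))), index=index, columns=INDICATOR_IDS
    )
    county = pd.Series(
        [f"240{1 + (i * n_counties) // n_tracts:02d}" for i in range(n_tracts)], index=index
    )
    return IndicatorTable(data, default_schema(), county=county)


@pytest.fixture(scope="session")
def demo_fixture():
    return bladensburg_like_demo()


@pytest.fixture(scope="session")
def region200():
    return generate_region(
        RegionConfig(n_tracts=200, severity_gradient=1.0, noise_sigma=0.1, seed=7)
    )
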