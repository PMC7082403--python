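import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from yieldgap.synthetic_data import SimConfig, SimulationResult, simulate_all

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

#: a small but fully structured simulated study, shared by unit tests
SMALL_CONFIG = SimConfig(
    n_orchards=6, plots_per_orchard_year=8, year_start=2009, year_end=2014, seed=7
)


@pytest.fixture(scope="session")
def small_sim() -> SimulationResult:
    return simulate_all(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_features(small_sim):
    from yieldgap.climate_features import build_feature_table

    features, manifest = build_feature_table(
        small_sim.dataset, small_sim.monthly, small_sim.daily, small_sim.cells
    )
    return features, manifest


def make_plot_rows(n: int, seed: int = 0) -> pd.DataFrame:
    """Valid plots.csv rows for loader tests."""
    rng = np.random.default_rng(seed)
    years = 2010 + rng.integers(0, 5, n)
    ages = rng.integers(1, 20, n)
    return pd.DataFrame(
        {
            "plot_id": [f"p{i:03d}" for i in range(n)],
            "orchard_id": [f"o{i % 3}" for i in range(n)],
            "year": years,
            "latitude": np.round(36 + rng.uniform(0, 3, n), 4),
            "longitude": np.round(-121 + rng.uniform(0, 2, n), 4),
            "cultivar_id": rng.choice([18, 17, 5], n),
            "planting_year": years - ages,
            "row_spacing_m": 6.7,
            "tree_spacing_m": 5.5,
            "light_interception": np.round(rng.uniform(0.1, 0.85, n), 4),
            "yield_kernel_lbs_acre": np.round(rng.uniform(300, 4500, n), 1),
        }
    )
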