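"""Shared fixtures: tiny hand-built landscapes and seeded synthetic ones."""

import numpy as np
import pandas as pd
import pytest

from policymix import (
    Landscape,
    ProfitModel,
    SyntheticConfig,
    calibrate_cell_distributions,
    generate_synthetic_landscape,
)


def make_landscape(cells: list[dict], districts: list[dict]) -> Landscape:
    """Build a landscape from plain dicts, filling schema defaults."""
    cdf = pd.DataFrame(cells)
    for col, default in [("area", 40_000.0), ("tc_first", 1000.0),
                         ("tc_within", 50.0)]:
        if col not in cdf.columns:
            cdf[col] = default
    ddf = pd.DataFrame(districts)
    return Landscape(cdf, ddf)


@pytest.fixture
def two_cell_landscape() -> Landscape:
    return make_landscape(
        cells=[
            {"cell_id": 1, "district_id": 10, "d0": 1000.0},
            {"cell_id": 2, "district_id": 10, "d0": 500.0},
        ],
        districts=[{"district_id": 10, "mean_profit": 600.0}],
    )


@pytest.fixture(scope="session")
def small_synthetic() -> Landscape:
    """20x20-cell landscape used for mid-size checks."""
    return generate_synthetic_landscape(
        SyntheticConfig(n_cells_x=20, n_cells_y=20, n_districts=10, seed=3))


@pytest.fixture(scope="session")
def default_synthetic() -> Landscape:
    """The 50x50-cell default landscape (study-region emulation)."""
    return generate_synthetic_landscape(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_model(default_synthetic) -> ProfitModel:
    return calibrate_cell_distributions(default_synthetic)


@pytest.fixture(scope="session")
def small_model(small_synthetic) -> ProfitModel:
    return calibrate_cell_distributions(small_synthetic)


def random_profit_model(rng: np.random.Generator, n: int = 4,
                        sigma_range=(200.0, 2000.0),
                        rate_range=(0.002, 0.3)) -> ProfitModel:
    """Random calibrated-style cell models with a common sigma."""
    from scipy.stats import norm

    sigma = rng.uniform(*sigma_range)
    rate = rng.uniform(*rate_range, n)
    area = np.full(n, 40_000.0)
    mu = sigma * norm.ppf(rate)
    return ProfitModel(mu=mu, sigma=np.full(n, sigma), area=area,
                       d0=rate * area)


def cells_frame(costs: np.ndarray) -> pd.DataFrame:
    """Minimal cells table where inspection cost equals ``costs`` exactly."""
    n = len(costs)
    return pd.DataFrame({"cell_id": np.arange(n), "tc_first": costs,
                         "tc_within": np.zeros(n), "n_patches": np.zeros(n)})
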