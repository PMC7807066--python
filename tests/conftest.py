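import warnings

import numpy as np
import pandas as pd
import pytest

from emusdm import (
    Grid,
    GridSurface,
    LandscapeSpec,
    PredictorStack,
    TrueNiche,
    generate_predictor_stack,
    make_hotspot_bias,
    sample_occurrences,
    true_suitability,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*Maximum iterations.*")


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    return Grid(n_rows=20, n_cols=25, cell_size_km=10.0)


@pytest.fixture(scope="session")
def small_stack() -> PredictorStack:
    spec = LandscapeSpec(
        n_rows=20,
        n_cols=25,
        cell_size_km=10.0,
        layer_names=("bio13", "bio15", "bio18"),
        autocorr_length_km=(50.0, 40.0, 30.0),
        seed=7,
    )
    return generate_predictor_stack(spec)


@pytest.fixture(scope="session")
def small_niche() -> TrueNiche:
    return TrueNiche(
        intercept=-0.5,
        coefficients={"bio13": 2.5, "bio15": -2.0},
        quadratic_coefficients={"bio13": -1.0},
    )


@pytest.fixture(scope="session")
def small_truth(small_stack, small_niche) -> GridSurface:
    return true_suitability(small_stack, small_niche)


@pytest.fixture(scope="session")
def uniform_surface(small_grid) -> GridSurface:
    return GridSurface(small_grid, np.ones(small_grid.shape))


@pytest.fixture(scope="session")
def small_presences(small_truth, small_stack) -> pd.DataFrame:
    bias = make_hotspot_bias(small_stack.grid, n_hotspots=3, floor=0.2, seed=3)
    return sample_occurrences(small_truth, bias, 120, seed=11, dirty_fraction=0.0)


@pytest.fixture(scope="session")
def separable_table() -> pd.DataFrame:
    """A cleanly separable two-predictor sample table for model tests."""
    rng = np.random.default_rng(42)
    n = 300
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    logit = 5.0 * x1 - 4.0 * x2
    y = (rng.uniform(size=n) < 1 / (1 + np.exp(-logit))).astype(int)
    # ensure both classes well represented
    return pd.DataFrame({"bio13": x1, "bio15": x2, "label": y})
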