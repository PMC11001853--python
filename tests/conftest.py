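import numpy as np
import pandas as pd
import pytest

from pelagichab.grids import GridSpec
from pelagichab.model import FitSettings


@pytest.fixture()
def small_grid() -> GridSpec:
    return GridSpec(lon_min=-96.0, lon_max=-90.0, lat_min=20.0, lat_max=26.0, cell_size=0.5)


@pytest.fixture()
def polygon(small_grid):
    return small_grid.to_polygon()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture()
def fast_settings() -> FitSettings:
    """Mode-only hyper integration and few draws: quick fits for unit tests."""
    return FitSettings(hyper_method="eb", max_hyper_evals=40, n_draws=120, seed=0)


@pytest.fixture(scope="session")
def study():
    """One small end-to-end synthetic study shared across tests."""
    from pelagichab.workflow import simulate_study

    return simulate_study(
        seed=5,
        n_sets=600,
        n_months=240,
        mesh_kwargs=dict(max_edge_inner=2.5, max_edge_outer=4.0, cutoff=0.8, extension=2.0),
    )


def make_offset_table(rng: np.random.Generator, n: int) -> pd.DataFrame:
    hooks = rng.integers(100, 1000, n)
    return pd.DataFrame({
        "hooks": hooks,
        "yft_count": rng.poisson(0.02 * hooks),
    })
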