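import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import enameloct as e

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cmap():
    return e.default_colormap()


@pytest.fixture(scope="session")
def clean_batch(cmap):
    """Small noiseless simulated batch spanning all four surface kinds."""
    return e.simulate_dataset(8, seed=11, speckle_sigma_db=0.0, width=120,
                              cmap=cmap)


@pytest.fixture(scope="session")
def speckled_batch(cmap):
    """Small speckled simulated batch."""
    return e.simulate_dataset(8, seed=12, speckle_sigma_db=1.5, width=120,
                              cmap=cmap)


@pytest.fixture()
def flat_sim(cmap):
    """One noiseless flat-surface frame."""
    params = e.SimulationParams()
    _, db = e.ma_line(params)
    surface = e.make_surface("F_sur", 60, row=4)
    return e.build_bscan(db, surface, cmap=cmap, params=params)


def make_bscan(values, **kw):
    return e.BScan(np.asarray(values, dtype=float), **kw)
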