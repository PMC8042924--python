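import numpy as np
import pytest

from rufflekit.volume_synth import SceneParams, synthesize_ruffle_scene
from rufflekit.wlc_sim import WLCParams


@pytest.fixture(scope="session")
def default_scene():
    """A deterministic 5-ruffle two-channel scene shared across tests."""
    params = SceneParams()
    series, truth = synthesize_ruffle_scene(params, seed=11)
    return params, series, truth


@pytest.fixture(scope="session")
def straight_sheet_scene():
    """A single gently-curved ruffle in a long field, for thickness/height tests."""
    params = SceneParams(
        volume_shape=(160, 60, 50),
        n_ruffles=1,
        backbone_params=WLCParams(l_p=50.0, contour_length=10.0, step=0.05),
        height_mean=3.0,
        height_sd=0.0,
        psf_sigma=(0.1, 0.1),
        n_channels=1,
    )
    series, truth = synthesize_ruffle_scene(params, seed=5)
    return params, series, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
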