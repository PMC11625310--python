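import numpy as np
import pytest

from faquant import SceneParams, generate_fa_scene


@pytest.fixture(scope="session")
def default_scene():
    """One default FA scene (12 objects, snr 10), reused across tests."""
    return generate_fa_scene(SceneParams(seed=7))


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free scene with perfectly colocalized channels."""
    params = SceneParams(rho_inner=1.0, rho_outer=1.0, snr=np.inf, seed=3)
    return generate_fa_scene(params)
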