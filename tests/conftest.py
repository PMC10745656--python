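import numpy as np
import pytest

from hld import synthetic


@pytest.fixture(scope="session")
def mixed_recording():
    """Clean four-activity session used by the vision/segmentation tests."""
    script = synthetic.ActivityScript(
        [(0, 5, "standing"), (5, 10, "walking"), (10, 15, "lying"), (15, 20, "running")]
    )
    return synthetic.generate_recording(
        script, noise=synthetic.NoiseConfig.silent(), seed=7
    )


@pytest.fixture(scope="session")
def rotation_recording():
    """Noiseless scripted rotation for orientation-recovery checks."""
    script = synthetic.ActivityScript([(0, 3, "standing"), (3, 9, "turning")])
    return synthetic.generate_recording(
        script, noise=synthetic.NoiseConfig.silent(), seed=11
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
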