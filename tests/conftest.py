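import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import imufall as f

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noise():
    return f.default_noise_model(seed=123)


@pytest.fixture(scope="session")
def quiet_noise():
    """Near-zero sensor noise for template-readback checks."""
    tiny = (1e-12, 1e-12, 1e-12)
    return f.NoiseModel(accel_sd=tiny, gyro_sd=tiny)


@pytest.fixture(scope="session")
def templates():
    return f.default_templates()


@pytest.fixture(scope="session")
def small_corpus(noise):
    """A 120-recording corpus (20 per class) for pipeline-level tests."""
    return f.generate_dataset(n_per_class=20, subjects=5, noise=noise, seed=99)


def constant_stream(acc=(1.0, 0.0, 0.0), gyro=(0.0, 0.0, 0.0), n=50, label=None):
    t = np.arange(n) / 100.0
    return f.ImuStream(
        t, np.tile(acc, (n, 1)), np.tile(gyro, (n, 1)), label=label
    )
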