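import numpy as np
import pytest

from rppgkit.synthetic import SyntheticSpec, constant_hr, default_bursts, generate_trace


@pytest.fixture(scope="session")
def clean_trace():
    """Noise-free, drift-free 72 bpm trace: ground truth for recovery checks."""
    spec = SyntheticSpec(duration=30.0, fps=30.0, noise_sigma=0.0, drift_amplitude=0.0, seed=1)
    return generate_trace(spec)


@pytest.fixture(scope="session")
def noisy_trace():
    """Default study conditions: drift + sensor noise + two artifact bursts."""
    spec = SyntheticSpec(duration=60.0, fps=30.0, seed=3, artifact_bursts=default_bursts(60.0))
    return generate_trace(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
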