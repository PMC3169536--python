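import numpy as np
import pytest

from clipcorrect.simulate import AcquisitionConfig, GroundTruthField


def gradient_truth(lo: float, hi: float, size: int = 128) -> GroundTruthField:
    """Horizontal linear intensity ramp from lo to hi."""
    return GroundTruthField(mu=np.tile(np.linspace(lo, hi, size), (size, 1)))


def constant_truth(value: float, size: int = 64) -> GroundTruthField:
    return GroundTruthField(mu=np.full((size, size), float(value)))


def fixed_sigma_config(sigma: float, **kwargs) -> AcquisitionConfig:
    """Acquisition whose noise is intensity-independent with the given sd."""
    return AcquisitionConfig(noise_a=0.0, noise_b=sigma**2, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
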