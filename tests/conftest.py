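import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from biofilm_kinetics import synthetic as syn
from biofilm_kinetics.io import ImageStack


@pytest.fixture
def small_stack() -> ImageStack:
    """20-frame 64×64 uint16 stack with ramped intensities."""
    rng = np.random.default_rng(7)
    data = rng.integers(0, 1000, size=(20, 64, 64), dtype=np.uint16)
    return ImageStack(data, pixel_size_um=0.869, dt_min=10.0, axes="TYX")


@pytest.fixture
def front_stack_noisy():
    """Noisy advancing front at 4.25 μm/min with its ground truth."""
    spec = syn.FrontSpec(rate_um_min=4.25, noise_sd=5.0, seed=11, n_frames=20)
    return syn.make_front_stack(spec)
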