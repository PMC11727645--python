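import numpy as np
import pytest

from vdmnet.model import ModelConfig
from vdmnet.synthetic import RenderParams, VesselTreeParams, generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cfg():
    """A desk-scale architecture: 3 levels, 8 base channels, 1 transformer level."""
    return ModelConfig(levels=3, base_channels=8, transformer_levels=1,
                       heads=2, experts=2, init_seed=0)


@pytest.fixture
def vessel_sample():
    """One deterministic 64x64 synthetic angiogram with its mask."""
    return generate_sample(VesselTreeParams(seed=0, height=64, width=64),
                           RenderParams(seed=0), "fixture")


def numerical_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of an array."""
    grad = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        grad[i] = (fp - fm) / (2 * eps)
    return grad
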