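import numpy as np
import pytest

from cacpnet.archspec import ArchSpec
from cacpnet.backbone import build_model


@pytest.fixture
def tiny_spec() -> ArchSpec:
    """A dollhouse backbone: same topology, few channels, 32-px input."""
    return ArchSpec(
        num_classes=3,
        stem_channels=8,
        stage_widths=[8, 12, 16, 16],
        blocks_per_stage=[1, 1, 1, 1],
        stage_strides=[1, 2, 2, 2],
        input_size=32,
    )


@pytest.fixture
def tiny_net(tiny_spec):
    return build_model(tiny_spec, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def numerical_gradient(f, arr: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference gradient of scalar-valued f() w.r.t. arr (in place)."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = arr[i]
        arr[i] = old + eps
        fp = f()
        arr[i] = old - eps
        fm = f()
        arr[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g
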