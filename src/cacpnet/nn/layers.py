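"""Layer containers: a small Module system over the autograd ops."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor
from . import ops

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear"]


class Module:
    """Base container: attribute-walking parameter/buffer discovery.

    Submodules are plain attributes (or lists of modules); parameters are
    :class:`Parameter` attributes; persistent buffers are registered by name
    in ``_buffer_names``.
    """

    def __init__(self):
        self.training = True
        self._buffer_names: list[str] = []

    # -- traversal ---------------------------------------------------------------
    def named_children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield (prefix + name, val)
        for cname, child in self.named_children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for bname in self._buffer_names:
            yield (prefix + bname, getattr(self, bname))
        for cname, child in self.named_children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self.named_children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- checkpointing -----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter in state dict: {name}")
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = np.array(state[name], dtype=p.data.dtype)
        for name, buf in self.named_buffers():
            if name in state:
                buf[...] = state[name]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Conv2d(Module):
    """Bias-free 2D convolution with Kaiming (fan-out) initialization."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng()
        fan_out = out_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_out)
        w = rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Parameter(w.astype(dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return ops.conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5, dtype=np.float32):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.weight = Parameter(np.ones(num_features, dtype=dtype))
        self.bias = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=np.float64)
        self.running_var = np.ones(num_features, dtype=np.float64)
        self._buffer_names = ["running_mean", "running_var"]

    def __call__(self, x: Tensor) -> Tensor:
        return ops.batchnorm2d(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        rng = rng or np.random.default_rng()
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(out_features, in_features)).astype(dtype))
        self.bias = Parameter(rng.uniform(-bound, bound, size=out_features).astype(dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return ops.linear(x, self.weight, self.bias)
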