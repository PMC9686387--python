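"""Minimal reverse-mode autodiff on numpy arrays.

A :class:`Tensor` wraps an ndarray plus an optional backward closure; ops in
:mod:`cacpnet.nn.ops` build the graph. Gradients flow only through tensors
with ``requires_grad`` (which propagates through ops), so inference-mode
forwards carry no graph. Intermediate tensors retain their gradient after
``backward()`` — class-activation mapping relies on that.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = (), name: str | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None  # callable(grad_out) -> None, accumulates into _prev
        self._prev = _prev
        self.name = name

    # -- ndarray-ish conveniences -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad}, name={self.name})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def accumulate_grad(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-accumulate gradients from this tensor through the graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        self.accumulate_grad(grad)
        # iterative topological sort (graphs are ~100s of nodes deep)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A trainable tensor (always requires grad)."""

    __slots__ = ()

    def __init__(self, data, name: str | None = None):
        super().__init__(np.asarray(data), requires_grad=True, name=name)
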