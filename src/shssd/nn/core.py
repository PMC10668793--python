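"""Minimal layer framework: modules own parameters and implement an explicit
forward/backward pair.

Every layer caches what its backward pass needs during ``forward`` and
releases the gradient of its input from ``backward``; parameter gradients
accumulate on ``Parameter.grad`` until ``zero_grad``.  All arithmetic is
float32 numpy.  There is no autograd graph — composite modules chain their
children's backward calls by hand, which keeps the dependency surface at
numpy alone and makes every gradient unit-checkable against finite
differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Parameter", "Module", "Sequential"]


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)

    @property
    def size(self) -> int:
        return self.data.size

    def __repr__(self) -> str:  # pragma: no cover
        return f"Parameter(shape={self.data.shape})"


class Module:
    """Base class: tracks child modules/parameters by attribute assignment."""

    def __init__(self):
        self.training = True

    # -- containers ---------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        """Count of trainable scalars (BN running statistics excluded)."""
        return sum(p.size for p in self.parameters())

    # -- mode / grads --------------------------------------------------
    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- serialization -------------------------------------------------
    def named_buffers(self, prefix: str = ""):
        """Non-trainable state (e.g. BN running statistics)."""
        for bname in getattr(self, "_buffer_names", ()):
            yield prefix + bname, getattr(self, bname)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self):
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: arr.copy() for name, arr in self.named_buffers()})
        return state

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for name, arr in self.named_buffers():
            arr[...] = state[name]

    # -- compute -------------------------------------------------------
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
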