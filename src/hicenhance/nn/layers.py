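"""Layer/module system on top of the autograd engine.

Mirrors the familiar container conventions: a :class:`Module` owns
parameters and submodules discovered by attribute, ``named_parameters``
walks the tree, and ``state_dict``/``load_state_dict`` round-trip through
plain dicts of arrays (serialized as NPZ archives of named arrays).
Weight sharing is expressed simply by assigning the same submodule object
in two places; the parameter walk deduplicates by object identity.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor

__all__ = ["Module", "Parameter", "Conv2d", "Linear", "LayerNorm", "Sequential", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        seen: set[int] = set()
        out = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        # first-seen name wins for shared parameters; loading restores all
        # aliases because they are the same object
        out: dict[str, np.ndarray] = {}
        seen: dict[int, str] = {}
        for name, p in self.named_parameters():
            if id(p) not in seen:
                seen[id(p)] = name
                out[name] = p.data.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {}
        for name, p in self.named_parameters():
            own.setdefault(name, p)
        loaded = set()
        for name, arr in state.items():
            if name not in own:
                raise KeyError(f"unexpected parameter {name!r}")
            if own[name].data.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: {own[name].data.shape} vs {arr.shape}"
                )
            own[name].data = np.asarray(arr, dtype=np.float32).copy()
            loaded.add(name)
        # names aliased to already-loaded shared objects are fine; anything
        # else unloaded is an error
        ids_loaded = {id(own[n]) for n in loaded}
        missing = [n for n, p in own.items() if id(p) not in ids_loaded]
        if missing:
            raise KeyError(f"missing parameters: {missing}")

    def save(self, path) -> None:
        np.savez_compressed(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as z:
            self.load_state_dict({k: z[k] for k in z.files})

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 2-D convolution with 'same' padding for odd kernels."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 padding: int | None = None, bias: bool = True):
        self.k = k
        self.padding = (k - 1) // 2 if padding is None else padding
        fan_in = c_in * k * k
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (c_out, c_in, k, k)))
        self.bias = Parameter(rng.uniform(-bound, bound, c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / math.sqrt(d_in)
        self.weight = Parameter(rng.uniform(-bound, bound, (d_in, d_out)))
        self.bias = Parameter(rng.uniform(-bound, bound, d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, self.eps)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999) with a mutable learning rate."""

    def __init__(self, params: list[Parameter], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
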