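"""Neural-network building blocks and the AdamW optimizer.

Thin layer over :mod:`wsf.autodiff`: modules own named parameter tensors,
initialization is driven by an explicit :class:`numpy.random.Generator`
(no global RNG state), and AdamW implements decoupled weight decay.
"""

from __future__ import annotations

import numpy as np

from .autodiff import DTYPE, Tensor, conv2d

__all__ = ["Module", "Linear", "Conv2d", "LayerNorm", "AdamW", "trunc_normal"]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) samples resampled into +-2 std (truncated normal)."""
    x = rng.standard_normal(shape) * std
    bad = np.abs(x) > 2 * std
    while bad.any():
        x[bad] = rng.standard_normal(bad.sum()) * std
        bad = np.abs(x) > 2 * std
    return x.astype(DTYPE)


class Module:
    """Base class: children and parameters discovered via attributes."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj, prefix):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    obj.name = obj.name or prefix
                    params.append(obj)
            elif isinstance(obj, Module):
                for name, value in vars(obj).items():
                    collect(value, f"{prefix}.{name}")
            elif isinstance(obj, (list, tuple)):
                for i, item in enumerate(obj):
                    collect(item, f"{prefix}[{i}]")

        collect(self, type(self).__name__)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)} parameters")
        for i, p in enumerate(params):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(DTYPE).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((in_features, out_features), dtype=DTYPE)
        else:
            w = trunc_normal(rng, (in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=DTYPE), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 zero_init: bool = False):
        shape = (out_ch, in_ch // groups, kernel, kernel)
        w = np.zeros(shape, dtype=DTYPE) if zero_init else trunc_normal(rng, shape)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True)
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class LayerNorm(Module):
    """Normalizes the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.weight = Tensor(np.ones(dim, dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(dim, dtype=DTYPE), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.weight + self.bias


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params: list[Tensor], lr: float = 6e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
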