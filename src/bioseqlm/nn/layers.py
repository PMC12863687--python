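"""Parameter containers and standard layers for the NumPy autodiff engine."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Tensor


class Module:
    """Base class: registers ``Tensor`` attributes (and sub-modules) as parameters."""

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                params[key] = value
            elif isinstance(value, Module):
                params.update(value.parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        params.update(item.parameters(f"{key}.{i}."))
        return params

    def zero_grad(self) -> None:
        for p in self.parameters().values():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"parameter name mismatch: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(DTYPE).copy()


class Linear(Module):
    """Affine map with 1/fan_in weight variance (the muP hidden-layer scheme)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, init_scale: float = 1.0):
        std = init_scale / np.sqrt(d_in)
        self.weight = Tensor(rng.normal(0.0, std, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    """Token embedding table with O(1) entries (muP embedding scheme)."""

    def __init__(self, n_tokens: int, d: int, rng: np.random.Generator, std: float = 1.0):
        self.weight = Tensor(rng.normal(0.0, std, size=(n_tokens, d)), requires_grad=True)

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids)]


class RMSNorm(Module):
    def __init__(self, d: int, eps: float = 1e-6):
        self.gain = Tensor(np.ones(d), requires_grad=True)
        self._eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        ms = (x * x).mean(axis=-1, keepdims=True)
        return x * (ms + self._eps) ** -0.5 * self.gain


class AdamW:
    """AdamW over named parameter groups with a shared multiplicative schedule."""

    def __init__(self, groups: list[dict], betas=(0.9, 0.95), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        # groups: [{"params": {name: Tensor}, "lr": float}, ...]
        self.groups = groups
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = {}
        self._v = {}
        for g in groups:
            for name, p in g["params"].items():
                self._m[name] = np.zeros_like(p.data)
                self._v[name] = np.zeros_like(p.data)

    def step(self, scale: float = 1.0) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for g in self.groups:
            lr = g["lr"] * scale
            for name, p in g["params"].items():
                if p.grad is None:
                    continue
                m = self._m[name]
                v = self._v[name]
                m *= b1
                m += (1.0 - b1) * p.grad
                v *= b2
                v += (1.0 - b2) * p.grad ** 2
                update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
                p.data -= lr * (update + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"].values():
                p.grad = None
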