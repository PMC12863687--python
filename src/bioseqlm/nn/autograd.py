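"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's neural components (transformer encoder, task heads, probes) are
small enough that a compact tape-based engine over BLAS-backed ``numpy``
operations is sufficient: every op stores its parents and a closure that
accumulates gradients into them.  Arrays are float32 throughout; gradients are
materialised lazily as float32 arrays of the same shape.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != DTYPE:
        a = a.astype(DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # ---------------------------------------------------------------- basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            # free intermediate grads eagerly? keep: optimizer reads leaves only

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))
        out._backward = lambda g: self._accum(g * exponent * self.data ** (exponent - 1.0))
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                if ga.shape != self.data.shape:
                    ga = _unbroadcast(ga, self.data.shape)
                self._accum(ga)
            if other.requires_grad:
                if self.data.ndim == 1:
                    gb = np.outer(self.data, g)
                else:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                if gb.shape != other.data.shape:
                    gb = _unbroadcast(gb, other.data.shape)
                other._accum(gb)

        out._backward = bw
        return out

    # ----------------------------------------------------------- elementwise
    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        od = out.data  # capture the array, not the tensor (avoids ref cycles)
        out._backward = lambda g: self._accum(g * od)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out = Tensor(np.tanh(self.data), parents=(self,))
        od = out.data
        out._backward = lambda g: self._accum(g * (1.0 - od ** 2))
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), parents=(self,))
        od = out.data
        out._backward = lambda g: self._accum(g * od * (1.0 - od))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        out._backward = lambda g: self._accum(g * (self.data > 0))
        return out

    def silu(self):
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, parents=(self,))
        out._backward = lambda g: self._accum(g * (sig * (1.0 + self.data * (1.0 - sig))))
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(DTYPE))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def swapaxes(self, a: int, b: int):
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))
        out._backward = lambda g: self._accum(np.swapaxes(g, a, b))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(acc, idx, g)
            self._accum(acc)

        out._backward = bw
        return out


# ------------------------------------------------------------------ functional
def concatenate(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = t if isinstance(t, Tensor) else Tensor(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(shape))
    return concatenate(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))  # detached max
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x + Tensor(-x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean negative log-likelihood of integer ``targets`` under ``logits``.

    ``logits`` has shape (..., C); ``targets`` the matching leading shape.
    ``weights`` (same leading shape) selects/weights positions; the loss is
    normalised by the total weight.
    """
    lsm = log_softmax(logits, axis=-1)
    flat = lsm.reshape(-1, logits.shape[-1])
    t = np.asarray(targets).reshape(-1)
    picked = flat[np.arange(t.size), t]
    if weights is None:
        return -picked.mean()
    w = np.asarray(weights, dtype=DTYPE).reshape(-1)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("cross_entropy: no positions selected by weights")
    return -(picked * Tensor(w)).sum() * (1.0 / total)


def binary_cross_entropy_with_logits(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Numerically stable BCE: max(z,0) - z*y + log(1 + exp(-|z|))."""
    z = logits
    y = Tensor(np.asarray(targets, dtype=DTYPE))
    abs_z = Tensor(np.abs(z.data))
    # log(1+exp(-|z|)) with detached |z| sign pattern; gradient flows via z
    sign = Tensor(np.sign(z.data))
    softplus = ((-(z * sign)).exp() + 1.0).log()
    loss = z.relu() - z * y + softplus
    if weights is None:
        return loss.mean()
    w = np.asarray(weights, dtype=DTYPE)
    total = float(w.sum())
    if total <= 0:
        raise ValueError("bce: no positions selected by weights")
    return (loss * Tensor(w)).sum() * (1.0 / total)


def conv2d_3x3(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """3x3 same-padded stride-1 2-D convolution, NCHW layout, via im2col.

    ``x``: (B, C_in, H, W); ``weight``: (C_out, C_in, 3, 3); output (B, C_out, H, W).
    """
    B, C, H, W = x.shape
    C_out = weight.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    # columns: (B, H, W, C*9)
    cols = np.empty((B, H, W, C, 9), dtype=DTYPE)
    k = 0
    for di in range(3):
        for dj in range(3):
            cols[..., k] = xp[:, :, di:di + H, dj:dj + W].transpose(0, 2, 3, 1)
            k += 1
    cols2 = cols.reshape(B * H * W, C * 9)
    wmat = weight.data.transpose(1, 2, 3, 0).reshape(C * 9, C_out)
    out_data = (cols2 @ wmat).reshape(B, H, W, C_out).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, C_out, 1, 1)
    parents = (x, weight) + ((bias,) if bias is not None else ())
    out = Tensor(out_data, parents=parents)

    def bw(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(B * H * W, C_out)
        if weight.requires_grad:
            gw = (cols2.T @ gmat).reshape(C, 3, 3, C_out).transpose(3, 0, 1, 2)
            weight._accum(gw)
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat.T).reshape(B, H, W, C, 9)
            gxp = np.zeros_like(xp)
            k = 0
            for di in range(3):
                for dj in range(3):
                    gxp[:, :, di:di + H, dj:dj + W] += gcols[..., k].transpose(0, 3, 1, 2)
                    k += 1
            x._accum(gxp[:, :, 1:-1, 1:-1])

    out._backward = bw
    return out
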