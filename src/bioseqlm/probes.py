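"""Interpretability probes over frozen model internals.

Two procedures, both of which leave the backbone untouched:

* **Contrastive modality-invariance probe.**  Given paired gene and protein
  embeddings (z_x, z_y), a low-rank linear map W (k x d, k=16) is trained with
  the symmetric CLIP objective at temperature tau=0.07 on a small fraction
  (5%) of the pairs; generalisation is read off the held-out 95% as the AUROC
  of matched vs mismatched cosine similarity.  A single shared W can only
  succeed if the two modalities already occupy a common subspace; the
  dual-probe control (separate W_x, W_y, one per modality, twice the
  parameters) is the comparison applied to single-omic encoders.

* **Frozen-attention convolutional contact probe.**  The full
  (n_layers*n_heads) x L x L attention stack is treated as image channels and
  passed through a 4-layer 3x3 conv net (channels -> 64 -> 64 -> 64 -> 1,
  zero same-padding); the L x L output is averaged over its last axis into L
  logits whose sigmoids are per-residue contact probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .nn import (AdamW, Tensor, binary_cross_entropy_with_logits, conv2d_3x3,
                 log_softmax, stack)

CLIP_TAU = 0.07
CLIP_RANK = 16


@dataclass
class EmbeddingPairSet:
    """Row i of X (gene embedding) corresponds to row i of Y (protein)."""

    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float32)
        self.Y = np.asarray(self.Y, dtype=np.float32)
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y must be N x d with matching shapes")
        if not (np.isfinite(self.X).all() and np.isfinite(self.Y).all()):
            raise ValueError("embeddings must be finite")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


def _project_normalize(Z: np.ndarray, W: Tensor) -> Tensor:
    proj = Tensor(Z) @ W.swapaxes(0, 1)  # (N, k)
    norms = (proj * proj).sum(axis=-1, keepdims=True) ** 0.5
    if (norms.data == 0).any():
        raise ValueError("zero-norm projected embedding")
    return proj / norms


def clip_loss(X: np.ndarray, Y: np.ndarray, W: Tensor, tau: float = CLIP_TAU,
              Wy: Tensor | None = None) -> Tensor:
    """Symmetric InfoNCE loss over a similarity matrix S_ij = <x_i, y_j>/tau.

    Row i of the projected, unit-normalised X should match row i of Y: the
    loss averages the row-wise and column-wise cross-entropies with label i.
    ``Wy`` switches to the dual-probe parameterisation (W projects X, Wy
    projects Y).
    """
    xh = _project_normalize(X, W)
    yh = _project_normalize(Y, Wy if Wy is not None else W)
    S = (xh @ yh.swapaxes(0, 1)) * (1.0 / tau)
    n = S.shape[0]
    labels = np.arange(n)
    row = log_softmax(S, axis=-1)[labels, labels]
    col = log_softmax(S.swapaxes(0, 1), axis=-1)[labels, labels]
    return -(row.mean() + col.mean()) * 0.5


@dataclass
class ProbeResult:
    W: np.ndarray
    Wy: np.ndarray | None
    auroc: float
    train_auroc: float
    matched: np.ndarray  # held-out matched cosine similarities
    mismatched: np.ndarray


def _similarities(X, Y, W, Wy=None):
    xh = _project_normalize(X, Tensor(W)).data
    yh = _project_normalize(Y, Tensor(Wy if Wy is not None else W)).data
    return xh @ yh.T


def _auroc_from_sims(S: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    n = S.shape[0]
    matched = np.diag(S)
    off = ~np.eye(n, dtype=bool)
    mismatched = S[off]
    labels = np.concatenate([np.ones(n), np.zeros(mismatched.size)])
    scores = np.concatenate([matched, mismatched])
    return float(roc_auc_score(labels, scores)), matched, mismatched


def train_probe(
    pairs: EmbeddingPairSet,
    mode: str = "joint_single_W",
    train_frac: float = 0.05,
    steps: int = 10000,
    lr: float = 0.01,
    rank: int = CLIP_RANK,
    tau: float = CLIP_TAU,
    seed: int = 0,
) -> ProbeResult:
    """Fit the contrastive probe on frozen embeddings and score held-out pairs.

    ``mode``: ``joint_single_W`` (one shared projection) or ``dual_W_control``
    (separate projections for the two modalities).  The learning rate decays
    linearly to zero.  Embeddings are never modified.
    """
    if mode not in ("joint_single_W", "dual_W_control"):
        raise ValueError(f"unknown mode {mode!r}")
    if rank * 4 >= pairs.d:
        raise ValueError("probe rank must satisfy k < d/4")
    rng = np.random.default_rng(seed)
    n_train = max(2, int(round(train_frac * pairs.n)))
    if pairs.n < n_train + 2:
        raise ValueError("too few pairs for a train/test split")
    order = rng.permutation(pairs.n)
    tr, te = order[:n_train], order[n_train:]
    Xtr, Ytr = pairs.X[tr], pairs.Y[tr]

    W = Tensor(rng.normal(0, 1.0 / np.sqrt(pairs.d), (rank, pairs.d)),
               requires_grad=True)
    Wy = None
    params = {"W": W}
    if mode == "dual_W_control":
        Wy = Tensor(rng.normal(0, 1.0 / np.sqrt(pairs.d), (rank, pairs.d)),
                    requires_grad=True)
        params["Wy"] = Wy
    opt = AdamW([{"params": params, "lr": lr}], betas=(0.9, 0.95), weight_decay=0.0)
    for step in range(steps):
        loss = clip_loss(Xtr, Ytr, W, tau, Wy)
        opt.zero_grad()
        loss.backward()
        opt.step(1.0 - step / steps)  # linear decay to zero

    auroc, matched, mismatched = _auroc_from_sims(
        _similarities(pairs.X[te], pairs.Y[te], W.data,
                      None if Wy is None else Wy.data))
    train_auroc, _, _ = _auroc_from_sims(
        _similarities(Xtr, Ytr, W.data, None if Wy is None else Wy.data))
    return ProbeResult(W.data.copy(), None if Wy is None else Wy.data.copy(),
                       auroc, train_auroc, matched, mismatched)


# ------------------------------------------------------ attention contact probe
@dataclass
class AttentionStack:
    """(n_layers * n_heads) x L x L attention channels for one complex."""

    channels: np.ndarray
    source: str = "base_model"

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3 or self.channels.shape[1] != self.channels.shape[2]:
            raise ValueError("attention stack must be C x L x L")


def stack_from_encoder_output(attentions: np.ndarray, source: str = "base_model",
                              token_slice: slice | None = None) -> AttentionStack:
    """Flatten a (n_layers, n_heads, L, L) export into C x L x L channels,
    optionally restricted to a token window (e.g. the protein block)."""
    a = np.asarray(attentions)
    if a.ndim == 5:  # batched export of a single row
        a = a[0]
    C = a.shape[0] * a.shape[1]
    channels = a.reshape(C, a.shape[2], a.shape[3])
    if token_slice is not None:
        channels = channels[:, token_slice, token_slice]
    return AttentionStack(channels, source)


class ConvContactProbe:
    """Four-layer convolutional read-out of attention stacks (frozen backbone).

    Inputs are standardised per channel with statistics frozen from the
    training stacks (attention weights live near 1/L, so without this affine
    rescaling the probe would first have to spend its budget re-scaling its
    own weights).
    """

    def __init__(self, in_channels: int, rng: np.random.Generator, hidden: int = 64):
        def conv(c_in, c_out):
            return Tensor(rng.normal(0, 1.0 / np.sqrt(9 * c_in), (c_out, c_in, 3, 3)),
                          requires_grad=True)

        self.convs = [conv(in_channels, hidden), conv(hidden, hidden),
                      conv(hidden, hidden), conv(hidden, 1)]
        self.input_mean = np.zeros(in_channels, dtype=np.float32)
        self.input_std = np.ones(in_channels, dtype=np.float32)

    def fit_input_scaling(self, stacks: list["AttentionStack"]) -> None:
        data = np.stack([s.channels for s in stacks])  # (N, C, L, L)
        self.input_mean = data.mean(axis=(0, 2, 3)).astype(np.float32)
        self.input_std = (data.std(axis=(0, 2, 3)) + 1e-8).astype(np.float32)

    def parameters(self) -> dict[str, Tensor]:
        return {f"conv{i}": w for i, w in enumerate(self.convs)}

    def logits(self, stacks: Tensor) -> Tensor:
        """``stacks``: (B, C, L, L) -> per-residue logits (B, L)."""
        C = len(self.input_mean)
        x = (stacks + Tensor(-self.input_mean.reshape(1, C, 1, 1))) \
            * Tensor(1.0 / self.input_std.reshape(1, C, 1, 1))
        for w in self.convs[:-1]:
            x = conv2d_3x3(x, w).relu()
        x = conv2d_3x3(x, self.convs[-1])  # (B, 1, L, L)
        B, _, L, _ = x.shape
        return x.reshape(B, L, L).mean(axis=-1)

    def predict(self, stack: AttentionStack) -> np.ndarray:
        z = self.logits(Tensor(stack.channels[None]))
        return 1.0 / (1.0 + np.exp(-z.data[0]))


def train_conv_probe(
    stacks: list[AttentionStack],
    labels: list[np.ndarray],
    steps: int = 1000,
    batch: int = 256,
    lr: float = 1e-3,
    hidden: int = 64,
    seed: int = 0,
) -> ConvContactProbe:
    """AdamW training of the conv probe with linear lr decay to zero.

    All stacks must share L (pad/crop upstream).  Labels are per-residue
    booleans over the same window the stacks cover.
    """
    if not stacks:
        raise ValueError("no training stacks")
    rng = np.random.default_rng(seed)
    probe = ConvContactProbe(stacks[0].channels.shape[0], rng, hidden)
    probe.fit_input_scaling(stacks)
    X = np.stack([s.channels for s in stacks])
    Y = np.stack([np.asarray(l, dtype=np.float32) for l in labels])
    opt = AdamW([{"params": probe.parameters(), "lr": lr}],
                betas=(0.9, 0.999), weight_decay=1e-2)
    n = len(stacks)
    for step in range(steps):
        idx = rng.integers(0, n, size=min(batch, n))
        logits = probe.logits(Tensor(X[idx]))
        loss = binary_cross_entropy_with_logits(logits, Y[idx])
        opt.zero_grad()
        loss.backward()
        opt.step(1.0 - step / steps)
    return probe


def compare_attention_sources(
    base_stacks: list[AttentionStack],
    finetuned_stacks: list[AttentionStack],
    labels: list[np.ndarray],
    n_train: int | None = None,
    steps: int = 500,
    batch: int = 8,
    seed: int = 0,
) -> dict[str, float]:
    """Train identical conv probes on two attention sources and report F1s.

    The contrast of interest is whether attention maps from a model
    fine-tuned on binding free energy carry more contact information than the
    base model's maps (``delta_f1 > 0`` if so).
    """
    n_train = n_train if n_train is not None else int(0.8 * len(labels))
    out = {}
    for name, stacks in (("base", base_stacks), ("finetuned", finetuned_stacks)):
        probe = train_conv_probe(stacks[:n_train], labels[:n_train],
                                 steps=steps, batch=batch, seed=seed)
        out[f"{name}_f1"] = evaluate_conv_probe(probe, stacks[n_train:],
                                                labels[n_train:])
    out["delta_f1"] = out["finetuned_f1"] - out["base_f1"]
    return out


def evaluate_conv_probe(probe: ConvContactProbe, stacks: list[AttentionStack],
                        labels: list[np.ndarray],
                        threshold: float | str = "best") -> float:
    """F1 of thresholded probe predictions over a fold.

    ``threshold="best"`` scores at the F1-maximising decision threshold (so an
    uninformative probe degrades to the all-positive baseline ``2p/(1+p)``
    rather than to 0); pass a float for a fixed threshold.
    """
    from .evaluation import metrics

    preds = np.concatenate([probe.predict(s) for s in stacks])
    truth = np.concatenate([np.asarray(l, dtype=float) for l in labels])
    if threshold == "best":
        candidates = np.unique(np.concatenate([preds, [0.5]]))
        return max(metrics((preds >= t).astype(float), truth, "f1")
                   for t in candidates)
    return metrics((preds >= threshold).astype(float), truth, "f1")
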