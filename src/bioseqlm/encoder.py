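"""Non-causal transformer encoder with rotary positions and muP scaling.

The architecture is a bidirectional (fully-visible) pre-norm transformer in
the LLaMA style: RMSNorm, rotary positional embeddings applied to queries and
keys, and a gated (SwiGLU) feed-forward block.  Two deliberate departures from
the common recipe implement maximal update parameterization (muP):

* pre-softmax attention scores are scaled by ``1/head_dim`` rather than
  ``1/sqrt(head_dim)``;
* embeddings are initialised with O(1) variance while all hidden linear maps
  use variance proportional to ``1/fan_in``.

Together with the 32/width learning-rate rule in :mod:`bioseqlm.pretraining`,
this keeps activation scales and optimal hyperparameters approximately stable
as the width is varied.

Every forward pass can export the complete stack of attention maps
(``n_layers x n_heads`` row-stochastic L x L matrices), which the
interpretability probes consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Embedding, Linear, Module, RMSNorm, Tensor, concatenate, softmax
from .tokenization import TokenizedSequence

NEG_INF = -1e9


@dataclass
class EncoderConfig:
    d: int
    n_layers: int
    n_heads: int
    vocab_size: int
    context_length: int = 1024
    rope_base: float = 10000.0

    def __post_init__(self):
        if self.d % self.n_heads:
            raise ValueError("width must be divisible by n_heads")

    @property
    def head_dim(self) -> int:
        return self.d // self.n_heads

    @property
    def attention_scale(self) -> float:
        # muP: 1/head_dim, not 1/sqrt(head_dim)
        return 1.0 / self.head_dim

    @property
    def ffn_hidden(self) -> int:
        return int(round(8.0 / 3.0 * self.d))


@dataclass
class EncoderOutput:
    """Hidden states plus the full layer x head attention stack.

    ``hidden`` keeps its autodiff graph so heads can backpropagate into the
    encoder; ``attentions`` is a detached ``(n_layers, n_heads, L, L)`` array
    (batched: ``(B, n_layers, n_heads, L, L)``) of row-stochastic maps.
    """

    hidden: Tensor  # (B, L, d)
    attentions: np.ndarray  # (B, n_layers, n_heads, L, L)


def rope_angles(config: EncoderConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-position cos/sin tables of shape (context_length, head_dim)."""
    hd = config.head_dim
    inv_freq = config.rope_base ** (-np.arange(0, hd, 2) / hd)
    t = np.arange(config.context_length)
    ang = np.outer(t, inv_freq)  # (L, hd/2)
    ang = np.concatenate([ang, ang], axis=-1)  # half-split convention
    return np.cos(ang).astype(np.float32), np.sin(ang).astype(np.float32)


def _rotate_half(x: Tensor) -> Tensor:
    half = x.shape[-1] // 2
    lead = (slice(None),) * (x.ndim - 1)
    x1 = x[lead + (slice(0, half),)]
    x2 = x[lead + (slice(half, None),)]
    return concatenate([-x2, x1], axis=-1)


class _Attention(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d = config.d
        self.wq = Linear(d, d, rng, bias=False)
        self.wk = Linear(d, d, rng, bias=False)
        self.wv = Linear(d, d, rng, bias=False)
        self.wo = Linear(d, d, rng, bias=False)
        self._config = config
        self._cos, self._sin = rope_angles(config)

    def __call__(self, x: Tensor, key_mask: np.ndarray):
        cfg = self._config
        B, L, d = x.shape
        H, hd = cfg.n_heads, cfg.head_dim

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, H, hd).transpose(0, 2, 1, 3)  # (B,H,L,hd)

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        cos = Tensor(self._cos[None, None, :L, :])
        sin = Tensor(self._sin[None, None, :L, :])
        q = q * cos + _rotate_half(q) * sin
        k = k * cos + _rotate_half(k) * sin
        scores = (q @ k.swapaxes(-1, -2)) * cfg.attention_scale
        bias = np.where(key_mask[:, None, None, :], 0.0, NEG_INF).astype(np.float32)
        attn = softmax(scores + Tensor(bias), axis=-1)  # (B,H,L,L)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(out), attn.data


class _SwiGLU(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        d, h = config.d, config.ffn_hidden
        self.w_gate = Linear(d, h, rng, bias=False)
        self.w_up = Linear(d, h, rng, bias=False)
        self.w_down = Linear(h, d, rng, bias=False)

    def __call__(self, x: Tensor) -> Tensor:
        return self.w_down(self.w_gate(x).silu() * self.w_up(x))


class _Block(Module):
    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.norm_attn = RMSNorm(config.d)
        self.attn = _Attention(config, rng)
        self.norm_ffn = RMSNorm(config.d)
        self.ffn = _SwiGLU(config, rng)

    def __call__(self, x: Tensor, key_mask: np.ndarray):
        a, maps = self.attn(self.norm_attn(x), key_mask)
        x = x + a
        x = x + self.ffn(self.norm_ffn(x))
        return x, maps


class Encoder(Module):
    """Masked-language-model backbone; see the module docstring."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.embed = Embedding(config.vocab_size, config.d, rng, std=1.0)
        self.blocks = [_Block(config, rng) for _ in range(config.n_layers)]
        self.norm_out = RMSNorm(config.d)
        self.unembed = Linear(config.d, config.vocab_size, rng, bias=False)

    # parameter groups for muP learning-rate rules -------------------------
    def embedding_parameters(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.parameters().items()
                if k.startswith(("embed.", "unembed."))}

    def hidden_parameters(self) -> dict[str, Tensor]:
        emb = self.embedding_parameters()
        return {k: v for k, v in self.parameters().items() if k not in emb}

    def forward(self, ids: np.ndarray, pad_mask: np.ndarray | None = None) -> EncoderOutput:
        """Run the encoder on a batch of id rows.

        ``ids``: (B, L) int array (or a single row, auto-promoted).
        ``pad_mask``: (B, L) booleans, True for real tokens; default all-True.
        """
        ids = np.asarray(ids)
        if ids.ndim == 1:
            ids = ids[None, :]
        B, L = ids.shape
        if L > self.config.context_length:
            raise ValueError(
                f"input length {L} exceeds context_length "
                f"{self.config.context_length}; truncate upstream")
        if pad_mask is None:
            pad_mask = np.ones((B, L), dtype=bool)
        x = self.embed(ids)
        maps = []
        for block in self.blocks:
            x, m = block(x, pad_mask)
            maps.append(m)
        hidden = self.norm_out(x)
        attentions = np.stack(maps, axis=1)  # (B, n_layers, H, L, L)
        return EncoderOutput(hidden=hidden, attentions=attentions)

    def forward_tokens(self, tokens: TokenizedSequence) -> EncoderOutput:
        return self.forward(np.asarray(tokens.ids, dtype=np.int64))

    def mlm_logits(self, output: EncoderOutput) -> Tensor:
        """Per-position unembedding scores, shape (B, L, vocab_size)."""
        return self.unembed(output.hidden)


def pooled_embedding(output: EncoderOutput) -> Tensor:
    """Embedding of the first token (the prepended classification token)."""
    if output.hidden.shape[-2] < 1:
        raise ValueError("empty sequence has no pooled embedding")
    if output.hidden.ndim == 2:
        return output.hidden[0]
    return output.hidden[:, 0]


def save_checkpoint(encoder: Encoder, path) -> None:
    import json
    from pathlib import Path

    path = Path(path)
    state = {k.replace(".", "__"): v for k, v in encoder.state_dict().items()}
    np.savez(path.with_suffix(".npz"), **state)
    cfg = encoder.config
    path.with_suffix(".json").write_text(json.dumps({
        "d": cfg.d, "n_layers": cfg.n_layers, "n_heads": cfg.n_heads,
        "vocab_size": cfg.vocab_size, "context_length": cfg.context_length,
        "rope_base": cfg.rope_base,
    }))


def load_checkpoint(path, rng: np.random.Generator | None = None) -> Encoder:
    import json
    from pathlib import Path

    path = Path(path)
    cfg = EncoderConfig(**json.loads(path.with_suffix(".json").read_text()))
    enc = Encoder(cfg, rng or np.random.default_rng(0))
    with np.load(path.with_suffix(".npz")) as data:
        enc.load_state_dict({k.replace("__", "."): data[k] for k in data.files})
    return enc
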