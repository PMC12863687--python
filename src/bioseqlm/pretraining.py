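"""Masked-language-model pretraining with modality-pure context packing.

Batches are packed greedily: each row of a batch holds one or more sequences
of a *single* modality, separated by that modality's separator token, so
protein and nucleic-acid ids never share a context window.  Corruption follows
the standard MLM recipe: a fraction ``mask_rate`` of non-special positions is
selected for loss; of those, 80% are replaced by the mask id, 10% by a random
piece id of the same modality, and 10% left unchanged.

Learning rates follow the muP prescription: the embedding/unembedding group
trains at a fixed rate (0.05) while every other parameter group is scaled by
32/width.  All groups share a one-cycle schedule that starts and ends at a
scale of 1e-5 and peaks at 1.0 after warmup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoder import Encoder
from .nn import AdamW, cross_entropy
from .tokenization import Modality, TokenizedSequence, Vocabulary

logger = logging.getLogger(__name__)


@dataclass
class MLMBatch:
    input_ids: np.ndarray  # (B, L)
    target_ids: np.ndarray  # (B, L)
    loss_mask: np.ndarray  # (B, L) bool: positions contributing to the loss
    pad_mask: np.ndarray  # (B, L) bool: real (non-pad) positions
    modalities: list[Modality]  # one per row


@dataclass
class OptimizerPlan:
    embedding_lr: float = 0.05
    hidden_lr_base: float = 0.05  # multiplied by 32/width
    adam_betas: tuple[float, float] = (0.9, 0.95)
    adam_eps: float = 1e-8
    weight_decay: float = 1e-2
    warmup_frac: float = 0.1
    start_end_scale: float = 1e-5

    def hidden_lr(self, width: int) -> float:
        return self.hidden_lr_base * 32.0 / width

    def build(self, encoder: Encoder) -> AdamW:
        return AdamW(
            [
                {"params": encoder.embedding_parameters(), "lr": self.embedding_lr},
                {"params": encoder.hidden_parameters(),
                 "lr": self.hidden_lr(encoder.config.d)},
            ],
            betas=self.adam_betas, eps=self.adam_eps, weight_decay=self.weight_decay,
        )


def lr_schedule(step: int, total_steps: int, warmup_steps: int,
                start_end_scale: float = 1e-5) -> float:
    """One-cycle multiplicative scale: cosine ramp up, cosine decay down.

    Exactly ``start_end_scale`` at step 0 and ``total_steps``; exactly 1.0 at
    ``warmup_steps``.  Out-of-range steps are clamped with a warning.
    """
    if step < 0 or step > total_steps:
        logger.warning("lr_schedule: step %d outside [0, %d]; clamping", step, total_steps)
        step = min(max(step, 0), total_steps)
    s0 = start_end_scale
    if step <= warmup_steps:
        frac = step / max(warmup_steps, 1)
        return s0 + (1.0 - s0) * 0.5 * (1.0 - np.cos(np.pi * frac))
    frac = (step - warmup_steps) / max(total_steps - warmup_steps, 1)
    return s0 + (1.0 - s0) * 0.5 * (1.0 + np.cos(np.pi * frac))


def _corrupt_row(ids: np.ndarray, vocab: Vocabulary, mask_rate: float,
                 rng: np.random.Generator,
                 mix: tuple[float, float, float] = (0.8, 0.1, 0.1)):
    special = np.isin(ids, list(vocab.special_ids.values()))
    candidates = ~special
    chosen = candidates & (rng.random(ids.shape) < mask_rate)
    inp = ids.copy()
    u = rng.random(ids.shape)
    to_mask = chosen & (u < mix[0])
    to_random = chosen & (u >= mix[0]) & (u < mix[0] + mix[1])
    inp[to_mask] = vocab.special_ids["mask"]
    if to_random.any():
        inp[to_random] = rng.integers(vocab.id_offset, vocab.id_offset + vocab.size,
                                      size=int(to_random.sum()))
    return inp, chosen


def make_mlm_batch(
    pool: list[TokenizedSequence],
    vocabularies: dict[Modality, Vocabulary],
    context_length: int,
    n_rows: int,
    mask_rate: float = 0.15,
    rng: np.random.Generator | None = None,
    mix: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> MLMBatch:
    """Sample, pack, and corrupt a batch from a tokenized pool."""
    if not pool:
        raise ValueError("empty sequence pool")
    rng = rng or np.random.default_rng()
    by_mod: dict[Modality, list[TokenizedSequence]] = {}
    for t in pool:
        by_mod.setdefault(t.modality, []).append(t)

    rows_in, rows_tgt, rows_loss, rows_pad, mods = [], [], [], [], []
    modalities = list(by_mod)
    for _ in range(n_rows):
        mod = modalities[rng.integers(len(modalities))]
        vocab = vocabularies[mod]
        seqs = by_mod[mod]
        row = [vocab.special_ids["cls"]]
        while len(row) < context_length:
            t = seqs[rng.integers(len(seqs))]
            take = min(len(t.ids), context_length - len(row))
            row.extend(t.ids[:take])  # overlong sequences truncated
            if len(row) < context_length:
                row.append(vocab.special_ids["sep"])
        row = row[:context_length]
        ids = np.asarray(row, dtype=np.int64)
        inp, chosen = _corrupt_row(ids, vocab, mask_rate, rng, mix)
        rows_in.append(inp)
        rows_tgt.append(ids)
        rows_loss.append(chosen)
        rows_pad.append(np.ones(context_length, dtype=bool))
        mods.append(mod)
    return MLMBatch(
        input_ids=np.stack(rows_in),
        target_ids=np.stack(rows_tgt),
        loss_mask=np.stack(rows_loss),
        pad_mask=np.stack(rows_pad),
        modalities=mods,
    )


def mlm_loss(encoder: Encoder, batch: MLMBatch):
    out = encoder.forward(batch.input_ids, batch.pad_mask)
    logits = encoder.mlm_logits(out)
    if not batch.loss_mask.any():
        raise ValueError("batch has no masked positions")
    return cross_entropy(logits, batch.target_ids, batch.loss_mask.astype(np.float32))


def pretrain(
    pool: list[TokenizedSequence],
    encoder: Encoder,
    vocabularies: dict[Modality, Vocabulary],
    n_steps: int,
    n_rows: int = 8,
    context_length: int | None = None,
    mask_rate: float = 0.15,
    plan: OptimizerPlan | None = None,
    seed: int = 0,
) -> list[tuple[int, int, float]]:
    """Run MLM pretraining; returns the loss trace [(step, tokens_seen, loss)].

    Fully deterministic given ``seed``.  Aborts with a diagnostic if the loss
    becomes non-finite.
    """
    plan = plan or OptimizerPlan()
    context_length = context_length or encoder.config.context_length
    rng = np.random.default_rng(seed)
    opt = plan.build(encoder)
    warmup = max(1, int(plan.warmup_frac * n_steps))
    trace = []
    tokens_seen = 0
    for step in range(n_steps):
        batch = make_mlm_batch(pool, vocabularies, context_length, n_rows,
                               mask_rate, rng)
        loss = mlm_loss(encoder, batch)
        value = loss.item()
        if not np.isfinite(value):
            raise RuntimeError(f"MLM loss diverged at step {step}: {value}")
        opt.zero_grad()
        loss.backward()
        opt.step(lr_schedule(step, n_steps, warmup, plan.start_end_scale))
        tokens_seen += int(batch.pad_mask.sum())
        trace.append((step, tokens_seen, value))
    return trace
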