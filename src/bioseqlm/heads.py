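"""Fine-tuning heads for protein-nucleic-acid tasks.

A complex is presented to the multi-omic encoder as one context window::

    [cls] protein tokens [sep] nucleic tokens ([sep] second nucleic tokens)

with protein ids drawn from the protein vocabulary and nucleic ids from the
nucleic vocabulary (the ranges are disjoint, so the modality boundary is
recoverable from the ids alone).  The binding free energy DG (kcal/mol) is
regressed from the embedding of the leading classification token; per-residue
contact tagging applies a linear-plus-sigmoid head to every protein token
position.  A dual-encoder single-omic control embeds the protein and nucleic
sequences with two separate encoders and regresses DG from the concatenated
pooled embeddings — it can model each side's marginal effect but not
protein-specific nucleic preferences, which is exactly the contrast it exists
to measure.

Fine-tuning uses AdamW with three muP-style learning-rate groups (head 1e-2,
embeddings 1e-3, remaining encoder parameters 1e-4 * 1024/width), all decayed
on a one-cycle schedule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoder import Encoder, EncoderOutput, pooled_embedding
from .evaluation import FoldAssignment, metrics
from .nn import (AdamW, Linear, Module, Tensor, binary_cross_entropy_with_logits,
                 concatenate, conv2d_3x3)
from .pretraining import lr_schedule
from .tokenization import Modality, Vocabulary, validate_sequence
from .transforms import aggregate_to_tokens, broadcast_to_residues

logger = logging.getLogger(__name__)


@dataclass
class ComplexRecord:
    """One protein + 1-2 nucleic-acid chains, with optional labels."""

    protein_seq: str
    nucleic_seqs: tuple[str, ...]
    dG: float | None = None  # kcal/mol
    contact_labels: np.ndarray | None = None  # per protein residue

    def __post_init__(self):
        self.nucleic_seqs = tuple(self.nucleic_seqs)
        if len(self.nucleic_seqs) not in (1, 2):
            raise ValueError("a complex carries one or two nucleic-acid chains")
        if not self.protein_seq or not all(self.nucleic_seqs):
            raise ValueError("empty protein or nucleic sequence")
        validate_sequence(self.protein_seq, Modality.PROTEIN)
        for s in self.nucleic_seqs:
            validate_sequence(s, Modality.NUCLEIC)
        if self.contact_labels is not None:
            self.contact_labels = np.asarray(self.contact_labels, dtype=bool)
            if len(self.contact_labels) != len(self.protein_seq):
                raise ValueError("contact labels must cover every protein residue")

    @property
    def group_key(self) -> str:
        return self.protein_seq


@dataclass
class MultiomicInput:
    ids: np.ndarray
    protein_token_slice: slice  # token positions holding protein content
    protein_spans: list[tuple[int, int]]  # residue spans of those tokens


def build_multiomic_input(
    record: ComplexRecord,
    protein_vocab: Vocabulary,
    nucleic_vocab: Vocabulary,
    context_length: int | None = None,
) -> MultiomicInput:
    """Tokenize a complex into the joint layout described in the module docs.

    Over-length inputs are truncated from the nucleic tail only (the protein
    is never cut); a warning is logged.
    """
    from .tokenization import encode

    if not record.protein_seq or not all(record.nucleic_seqs):
        raise ValueError("empty protein or nucleic sequence")
    prot = encode(record.protein_seq, protein_vocab)
    ids: list[int] = [protein_vocab.special_ids["cls"]]
    ids.extend(prot.ids)
    prot_slice = slice(1, 1 + len(prot.ids))
    ids.append(protein_vocab.special_ids["sep"])
    for i, seq in enumerate(record.nucleic_seqs):
        if i > 0:
            ids.append(nucleic_vocab.special_ids["sep"])
        ids.extend(encode(seq, nucleic_vocab).ids)
    if context_length is not None and len(ids) > context_length:
        if prot_slice.stop + 2 > context_length:
            raise ValueError("protein alone exceeds the context window")
        logger.warning("truncating nucleic tail: %d -> %d tokens", len(ids), context_length)
        ids = ids[:context_length]
    return MultiomicInput(np.asarray(ids, dtype=np.int64), prot_slice, prot.spans)


def _pad_batch(id_rows: list[np.ndarray], pad_id: int):
    L = max(len(r) for r in id_rows)
    ids = np.full((len(id_rows), L), pad_id, dtype=np.int64)
    mask = np.zeros((len(id_rows), L), dtype=bool)
    for i, r in enumerate(id_rows):
        ids[i, :len(r)] = r
        mask[i, :len(r)] = True
    return ids, mask


@dataclass
class FinetuneLRs:
    head: float = 1e-2
    embeddings: float = 1e-3
    body_base: float = 1e-4  # multiplied by 1024/width

    def body(self, width: int) -> float:
        return self.body_base * 1024.0 / width


class RegressionHead(Module):
    def __init__(self, d: int, rng: np.random.Generator):
        self.proj = Linear(d, 1, rng, bias=True)

    def __call__(self, pooled: Tensor) -> Tensor:
        return self.proj(pooled).reshape(-1)


class DGModel(Module):
    """Joint multi-omic DG regressor: encoder + first-token linear head."""

    def __init__(self, encoder: Encoder, protein_vocab: Vocabulary,
                 nucleic_vocab: Vocabulary, rng: np.random.Generator):
        self.encoder = encoder
        self.head = RegressionHead(encoder.config.d, rng)
        self._pv = protein_vocab
        self._nv = nucleic_vocab

    def _batch(self, records: list[ComplexRecord]):
        rows = [build_multiomic_input(r, self._pv, self._nv,
                                      self.encoder.config.context_length).ids
                for r in records]
        return _pad_batch(rows, self._pv.special_ids["pad"])

    def predict_batch(self, records: list[ComplexRecord]) -> Tensor:
        ids, mask = self._batch(records)
        out = self.encoder.forward(ids, mask)
        return self.head(pooled_embedding(out))

    def predict_dG(self, record: ComplexRecord) -> float:
        return float(self.predict_batch([record]).data[0])

    def optimizer(self, lrs: FinetuneLRs) -> AdamW:
        return AdamW([
            {"params": self.head.parameters("head."), "lr": lrs.head},
            {"params": self.encoder.embedding_parameters(), "lr": lrs.embeddings},
            {"params": self.encoder.hidden_parameters(),
             "lr": lrs.body(self.encoder.config.d)},
        ])


class DualEncoderDGModel(Module):
    """Single-omic control: separate encoders, concatenated pooled embeddings."""

    def __init__(self, protein_encoder: Encoder, nucleic_encoder: Encoder,
                 protein_vocab: Vocabulary, nucleic_vocab: Vocabulary,
                 rng: np.random.Generator):
        self.protein_encoder = protein_encoder
        self.nucleic_encoder = nucleic_encoder
        self.head = Linear(protein_encoder.config.d + nucleic_encoder.config.d, 1,
                           rng, bias=True)
        self._pv = protein_vocab
        self._nv = nucleic_vocab

    def predict_batch(self, records: list[ComplexRecord]) -> Tensor:
        from .tokenization import encode

        prot_rows, nuc_rows = [], []
        for r in records:
            prot_rows.append(np.asarray(
                [self._pv.special_ids["cls"]] + encode(r.protein_seq, self._pv).ids))
            nuc_ids = [self._nv.special_ids["cls"]]
            for i, seq in enumerate(r.nucleic_seqs):
                if i > 0:
                    nuc_ids.append(self._nv.special_ids["sep"])
                nuc_ids.extend(encode(seq, self._nv).ids)
            nuc_rows.append(np.asarray(nuc_ids))
        pids, pmask = _pad_batch(prot_rows, self._pv.special_ids["pad"])
        nids, nmask = _pad_batch(nuc_rows, self._nv.special_ids["pad"])
        zp = pooled_embedding(self.protein_encoder.forward(pids, pmask))
        zn = pooled_embedding(self.nucleic_encoder.forward(nids, nmask))
        return self.head(concatenate([zp, zn], axis=-1)).reshape(-1)

    def predict_dG(self, record: ComplexRecord) -> float:
        return float(self.predict_batch([record]).data[0])

    def optimizer(self, lrs: FinetuneLRs) -> AdamW:
        groups = [{"params": self.head.parameters("head."), "lr": lrs.head}]
        for tag, enc in (("p", self.protein_encoder), ("n", self.nucleic_encoder)):
            groups.append({"params": {f"{tag}.{k}": v for k, v in
                                      enc.embedding_parameters().items()},
                           "lr": lrs.embeddings})
            groups.append({"params": {f"{tag}.{k}": v for k, v in
                                      enc.hidden_parameters().items()},
                           "lr": lrs.body(enc.config.d)})
        return AdamW(groups)


def _fit_regression(model, records: list[ComplexRecord], epochs: int, batch: int,
                    lrs: FinetuneLRs, seed: int) -> None:
    rng = np.random.default_rng(seed)
    opt = model.optimizer(lrs)
    steps_per_epoch = max(1, int(np.ceil(len(records) / batch)))
    total = epochs * steps_per_epoch
    warmup = max(1, total // 10)
    step = 0
    targets = np.asarray([r.dG for r in records], dtype=np.float32)
    for _ in range(epochs):
        order = rng.permutation(len(records))
        for lo in range(0, len(records), batch):
            idx = order[lo:lo + batch]
            pred = model.predict_batch([records[i] for i in idx])
            err = pred - Tensor(targets[idx])
            loss = (err * err).mean()
            opt.zero_grad()
            loss.backward()
            opt.step(lr_schedule(step, total, warmup))
            step += 1


def evaluate_dG(model, records: list[ComplexRecord]) -> dict[str, float]:
    preds = np.concatenate([model.predict_batch(records[lo:lo + 64]).data
                            for lo in range(0, len(records), 64)])
    truth = np.asarray([r.dG for r in records])
    return {"pcc": metrics(preds, truth, "pcc"), "mae": metrics(preds, truth, "mae")}


def finetune_dG(
    model,
    records: list[ComplexRecord],
    folds: FoldAssignment,
    eval_folds: list[int] | None = None,
    epochs: int = 64,
    batch: int = 256,
    lrs: FinetuneLRs | None = None,
    seed: int = 0,
    reset_state: dict | None = None,
) -> dict[int, dict[str, float]]:
    """Cross-validated DG fine-tuning; returns {fold: {"pcc", "mae"}}.

    ``model`` is a :class:`DGModel` or :class:`DualEncoderDGModel`.  The model
    is re-initialised from ``reset_state`` (a ``state_dict``) before each fold
    so folds do not contaminate each other.  ``eval_folds`` restricts which
    folds are trained/evaluated (useful at desk scale).
    """
    lrs = lrs or FinetuneLRs()
    results: dict[int, dict[str, float]] = {}
    fold_ids = eval_folds if eval_folds is not None else list(range(folds.n_folds))
    for fold in fold_ids:
        test_groups = folds.test_groups(fold)
        if not test_groups:
            raise ValueError(f"fold {fold} has no test proteins")
        train = [r for r in records if r.protein_seq not in test_groups]
        test = [r for r in records if r.protein_seq in test_groups]
        if reset_state is not None:
            model.load_state_dict(reset_state)
        _fit_regression(model, train, epochs, batch, lrs, seed + fold)
        results[fold] = evaluate_dG(model, test)
    return results


# --------------------------------------------------------- per-residue contacts
class ContactTaggingModel(Module):
    """Per-token contact classifier over the joint protein+nucleic context."""

    def __init__(self, encoder: Encoder, protein_vocab: Vocabulary,
                 nucleic_vocab: Vocabulary, rng: np.random.Generator):
        self.encoder = encoder
        self.head = Linear(encoder.config.d, 1, rng, bias=True)
        self._pv = protein_vocab
        self._nv = nucleic_vocab

    def _forward_one(self, record: ComplexRecord):
        inp = build_multiomic_input(record, self._pv, self._nv,
                                    self.encoder.config.context_length)
        out = self.encoder.forward(inp.ids)
        h = out.hidden[0][inp.protein_token_slice]  # protein tokens only
        return self.head(h).reshape(-1), inp

    def predict_contacts_per_residue(self, record: ComplexRecord) -> np.ndarray:
        logits, inp = self._forward_one(record)
        probs = 1.0 / (1.0 + np.exp(-logits.data))
        return broadcast_to_residues(probs, inp.protein_spans)

    def optimizer(self, lrs: FinetuneLRs) -> AdamW:
        return AdamW([
            {"params": self.head.parameters("head."), "lr": lrs.head},
            {"params": self.encoder.embedding_parameters(), "lr": lrs.embeddings},
            {"params": self.encoder.hidden_parameters(),
             "lr": lrs.body(self.encoder.config.d)},
        ])


def finetune_contacts(
    model: ContactTaggingModel,
    records: list[ComplexRecord],
    epochs: int = 32,
    batch: int = 256,
    lrs: FinetuneLRs | None = None,
    seed: int = 0,
) -> None:
    """Binary cross-entropy training of the per-residue contact tagger.

    Per-residue labels are aggregated to token space (mode within each token's
    span) before computing the loss, mirroring how predictions are broadcast
    back to residues at evaluation time.
    """
    for r in records:
        if r.contact_labels is None:
            raise ValueError("contact labels required for training")
    lrs = lrs or FinetuneLRs()
    rng = np.random.default_rng(seed)
    opt = model.optimizer(lrs)
    steps_per_epoch = max(1, int(np.ceil(len(records) / batch)))
    total = epochs * steps_per_epoch
    warmup = max(1, total // 10)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(records))
        for lo in range(0, len(records), batch):
            losses = []
            for i in order[lo:lo + batch]:
                record = records[i]
                logits, inp = model._forward_one(record)
                token_labels = aggregate_to_tokens(
                    record.contact_labels.astype(int), inp.protein_spans,
                    "classification")
                losses.append(binary_cross_entropy_with_logits(
                    logits, token_labels.astype(np.float32)))
            loss = sum(losses[1:], losses[0]) * (1.0 / len(losses))
            opt.zero_grad()
            loss.backward()
            opt.step(lr_schedule(step, total, warmup))
            step += 1


# ------------------------------------------------------------ pairwise contacts
class PairwiseContactHead(Module):
    """TAPE-style residue-residue contact head over a single protein.

    Each position's embedding is projected to 128 dimensions; pair features
    concatenate vector i with vector j into a 256-channel L x L grid, which an
    8-layer residual 3x3 conv stack reduces to a 1 x L x L logit map.  The
    training loss is masked to pairs separated by at least ``min_separation``
    residues.
    """

    min_separation = 12

    def __init__(self, d: int, rng: np.random.Generator, proj_dim: int = 128,
                 channels: int = 64):
        self.proj = Linear(d, proj_dim, rng, bias=True)
        self.conv_in = Tensor(rng.normal(0, 0.05, (channels, 2 * proj_dim, 3, 3)),
                              requires_grad=True)
        self.res_convs = [Tensor(rng.normal(0, 0.05, (channels, channels, 3, 3)),
                                 requires_grad=True) for _ in range(6)]
        self.conv_out = Tensor(rng.normal(0, 0.05, (1, channels, 3, 3)),
                               requires_grad=True)

    def __call__(self, hidden: Tensor) -> Tensor:
        """``hidden``: (L, d) protein-token states -> (L, L) contact logits."""
        L = hidden.shape[0]
        v = self.proj(hidden)  # (L, 128)
        vi = v.reshape(L, 1, -1) * Tensor(np.ones((1, L, 1), dtype=np.float32))
        vj = v.reshape(1, L, -1) * Tensor(np.ones((L, 1, 1), dtype=np.float32))
        pair = concatenate([vi, vj], axis=-1)  # (L, L, 256)
        x = pair.transpose(2, 0, 1).reshape(1, -1, L, L)
        x = conv2d_3x3(x, self.conv_in).relu()
        for a, b in zip(self.res_convs[0::2], self.res_convs[1::2]):
            y = conv2d_3x3(x, a).relu()
            x = x + conv2d_3x3(y, b)
            x = x.relu()
        logits = conv2d_3x3(x, self.conv_out)
        return logits.reshape(L, L)

    def loss_mask(self, L: int) -> np.ndarray:
        if L < self.min_separation + 1:
            raise ValueError(
                f"protein of length {L} has no pairs separated by "
                f">= {self.min_separation} residues")
        i = np.arange(L)
        return np.abs(i[:, None] - i[None, :]) >= self.min_separation


def predict_contact_map(encoder: Encoder, head: PairwiseContactHead,
                        tokens) -> np.ndarray:
    """Contact probability map for one protein (values in (0, 1))."""
    out = encoder.forward_tokens(tokens)
    logits = head(out.hidden[0])
    return 1.0 / (1.0 + np.exp(-logits.data))


# --------------------------------------------------------------- classification
class ClassificationModel(Module):
    """First-token classifier (the generic GUE/TAPE-style harness)."""

    def __init__(self, encoder: Encoder, vocab: Vocabulary, n_classes: int,
                 rng: np.random.Generator):
        self.encoder = encoder
        self.head = Linear(encoder.config.d, n_classes, rng, bias=True)
        self._vocab = vocab

    def predict_logits(self, sequences: list[str]) -> Tensor:
        from .tokenization import encode

        rows = [np.asarray([self._vocab.special_ids["cls"]]
                           + encode(s, self._vocab).ids) for s in sequences]
        ids, mask = _pad_batch(rows, self._vocab.special_ids["pad"])
        out = self.encoder.forward(ids, mask)
        return self.head(pooled_embedding(out))

    def optimizer(self, lrs: FinetuneLRs) -> AdamW:
        return AdamW([
            {"params": self.head.parameters("head."), "lr": lrs.head},
            {"params": self.encoder.embedding_parameters(), "lr": lrs.embeddings},
            {"params": self.encoder.hidden_parameters(),
             "lr": lrs.body(self.encoder.config.d)},
        ])


def finetune_classify(model: ClassificationModel, sequences: list[str],
                      labels: np.ndarray, epochs: int = 8, batch: int = 32,
                      lrs: FinetuneLRs | None = None, seed: int = 0) -> None:
    from .nn import cross_entropy

    lrs = lrs or FinetuneLRs()
    rng = np.random.default_rng(seed)
    opt = model.optimizer(lrs)
    labels = np.asarray(labels)
    steps_per_epoch = max(1, int(np.ceil(len(sequences) / batch)))
    total = epochs * steps_per_epoch
    warmup = max(1, total // 10)
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(sequences))
        for lo in range(0, len(sequences), batch):
            idx = order[lo:lo + batch]
            logits = model.predict_logits([sequences[i] for i in idx])
            loss = cross_entropy(logits, labels[idx])
            opt.zero_grad()
            loss.backward()
            opt.step(lr_schedule(step, total, warmup))
            step += 1
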