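"""Per-residue <-> per-token transforms for byte-pair tokenized labels.

BPE tokens usually cover several residues, so per-residue targets must be
aggregated to token space for training (mode for classification, mean for
regression) and token predictions broadcast back to residue space for
evaluation (each token's value duplicated over the residues it covers).
Contact maps and the short-range contact mask have analogous 2-D transforms.
All functions take the half-open character ``spans`` recorded by the
tokenizer, which tile ``[0, n_residues)``.
"""

from __future__ import annotations

import numpy as np

Spans = list[tuple[int, int]]


def _check_spans(spans: Spans, n_residues: int | None = None) -> int:
    pos = 0
    for start, end in spans:
        if start != pos or end <= start:
            raise ValueError("spans must tile [0, n) contiguously")
        pos = end
    if n_residues is not None and pos != n_residues:
        raise ValueError(f"spans cover {pos} residues, labels cover {n_residues}")
    return pos


def aggregate_to_tokens(residue_labels: np.ndarray, spans: Spans, task: str) -> np.ndarray:
    """Collapse per-residue labels to one value per token.

    ``task="classification"``: per-span mode, ties broken toward the lowest
    class id.  ``task="regression"``: per-span arithmetic mean.
    """
    labels = np.asarray(residue_labels)
    _check_spans(spans, len(labels))
    out = []
    for start, end in spans:
        chunk = labels[start:end]
        if task == "classification":
            values, counts = np.unique(chunk, return_counts=True)
            out.append(values[np.argmax(counts)])  # np.unique sorts -> lowest id wins ties
        elif task == "regression":
            out.append(chunk.mean())
        else:
            raise ValueError(f"unknown task {task!r}")
    return np.asarray(out)


def broadcast_to_residues(token_values: np.ndarray, spans: Spans) -> np.ndarray:
    """Duplicate each token's value over the residues its span covers."""
    values = np.asarray(token_values)
    if len(values) != len(spans):
        raise ValueError("one value per token required")
    n = _check_spans(spans)
    out = np.empty(n, dtype=values.dtype)
    for value, (start, end) in zip(values, spans):
        out[start:end] = value
    return out


def contact_map_to_token_space(residue_map: np.ndarray, spans: Spans) -> np.ndarray:
    """Token pair (i, j) is a contact iff any residue of i contacts any of j."""
    m = np.asarray(residue_map, dtype=bool)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("residue map must be square")
    _check_spans(spans, m.shape[0])
    T = len(spans)
    out = np.zeros((T, T), dtype=bool)
    for i, (si, ei) in enumerate(spans):
        for j, (sj, ej) in enumerate(spans):
            out[i, j] = m[si:ei, sj:ej].any()
    return out


def contact_mask_to_token_space(spans: Spans, min_separation: int = 12) -> np.ndarray:
    """Loss mask in token space: True iff some residue pair across the two
    tokens is at least ``min_separation`` residues apart (|r - s| >= 12)."""
    _check_spans(spans)
    T = len(spans)
    out = np.zeros((T, T), dtype=bool)
    for i, (si, ei) in enumerate(spans):
        for j, (sj, ej) in enumerate(spans):
            # max |r - s| over the two spans is attained at the extremes
            far = max(abs(si - (ej - 1)), abs((ei - 1) - sj))
            out[i, j] = far >= min_separation
    return out


def contact_map_to_residue_space(token_map: np.ndarray, spans: Spans) -> np.ndarray:
    """Residue pair (n, m) inherits the value of its covering token pair."""
    t = np.asarray(token_map)
    if t.ndim != 2 or t.shape[0] != t.shape[1] or t.shape[0] != len(spans):
        raise ValueError("token map must be square with one row per span")
    n = _check_spans(spans)
    out = np.empty((n, n), dtype=t.dtype)
    for i, (si, ei) in enumerate(spans):
        for j, (sj, ej) in enumerate(spans):
            out[si:ei, sj:ej] = t[i, j]
    return out
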