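"""Consensus extraction and mutation scanning for binding specificity.

A DNA-binding protein's position-frequency matrix (PFM) summarises its
preferred sites; the consensus is the per-column most frequent base.  The
mutation scan perturbs the consensus lightly (5% per-position substitution),
predicts the binding free energy of each mutant, and reports
``DDG_j = DG(mutant_j) - DG(consensus)``.  A model that has learned the
specificity should predict DDG > 0 on average: mutating away from the
consensus weakens binding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

BASES = "ACGT"


@dataclass
class PFM:
    """4 x W count matrix, rows ordered A, C, G, T."""

    counts: np.ndarray
    identifier: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ValueError("PFM counts must be a 4 x W matrix")
        if self.counts.shape[1] < 1 or (self.counts < 0).any():
            raise ValueError("PFM needs W >= 1 non-negative columns")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


def consensus_from_pfm(pfm: PFM) -> str:
    """Per-column argmax base; ties resolve alphabetically (A < C < G < T)."""
    if (pfm.counts.sum(axis=0) == 0).any():
        raise ValueError("PFM has an all-zero column")
    return "".join(BASES[i] for i in np.argmax(pfm.counts, axis=0))


def mutate_consensus(
    consensus: str,
    p: float = 0.05,
    n_mutants: int = 8,
    rng: np.random.Generator | None = None,
    require_change: bool = True,
    max_tries: int = 10000,
) -> list[str]:
    """Mutated copies of the consensus.

    Each position is independently substituted with probability ``p`` to a
    uniformly random different base.  With ``require_change=True`` (the
    default), draws identical to the consensus or to a previously accepted
    mutant are rejected and resampled, so the returned mutants are unique and
    each differs from the consensus in at least one position (this biases the
    per-mutant substitution count slightly above the unconditional binomial
    mean p*W).  ``require_change=False`` returns the raw independent draws.
    """
    if not consensus:
        raise ValueError("empty consensus")
    W = len(consensus)
    if require_change and n_mutants > 4 ** W - 1:
        raise ValueError(f"cannot draw {n_mutants} unique mutants of a width-{W} site")
    rng = rng or np.random.default_rng()
    mutants: list[str] = []
    for _ in range(max_tries):
        s = list(consensus)
        for w in range(W):
            if rng.random() < p:
                s[w] = rng.choice([b for b in BASES if b != s[w]])
        m = "".join(s)
        if not require_change or (m != consensus and m not in mutants):
            mutants.append(m)
        if len(mutants) == n_mutants:
            return mutants
    raise RuntimeError("rejection sampling failed to find unique mutants")


@dataclass
class ScanResult:
    identifier: str
    consensus: str
    ddg: np.ndarray  # one value per mutant, kcal/mol

    @property
    def mean_ddg(self) -> float:
        return float(self.ddg.mean())


def ddg_scan(
    predict_dG: Callable[[str, str], float],
    dbp_protein: str,
    pfm: PFM,
    p: float = 0.05,
    n_mutants: int = 8,
    rng: np.random.Generator | None = None,
) -> ScanResult:
    """Mutation scan for one DNA-binding protein.

    ``predict_dG(protein, nucleic) -> kcal/mol`` may be a fine-tuned model's
    predictor or a ground-truth oracle; using the same scan path for both is
    what lets tests pin the expected sign exactly.
    """
    consensus = consensus_from_pfm(pfm)
    mutants = mutate_consensus(consensus, p=p, n_mutants=n_mutants, rng=rng)
    ref = predict_dG(dbp_protein, consensus)
    ddg = np.asarray([predict_dG(dbp_protein, m) - ref for m in mutants])
    return ScanResult(pfm.identifier, consensus, ddg)
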