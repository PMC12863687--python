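"""Homology-aware evaluation utilities.

Cross-validation on protein-nucleic-acid complexes is only meaningful if
near-identical proteins never straddle the train/test boundary.  Splitting
therefore works on *protein groups* (records sharing the exact protein
sequence), measures homology with a BLOSUM62 global alignment score normalised
by alignment length, and pins every protein involved in a pair scoring above a
threshold (default 1.5 score/position) to the train side of all folds.  For
reference, an identical pair of typical composition scores about 5.2 under
this normalisation, while unrelated sequences score below 0.

Also here: distance-threshold contact labeling from 3-D structures, the
analytic random-guessing F1 ceiling, and the scalar metrics used across the
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

PINNED_TRAIN = -1

_PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_NUCLEIC_RESNAMES = {"A", "C", "G", "U", "DA", "DC", "DG", "DT", "DU"}


@dataclass(frozen=True)
class AlignmentScore:
    raw: float
    length: int

    @property
    def normalized(self) -> float:
        return self.raw / self.length


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def normalized_alignment_score(
    a: str, b: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> AlignmentScore:
    """BLOSUM62 global (end-to-end) alignment score per aligned position.

    Arguments are ordered canonically before aligning so the score is exactly
    symmetric even when optimal alignments are tied.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if b < a:
        a, b = b, a
    aligner = _make_aligner(gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    return AlignmentScore(raw=float(alignment.score), length=int(alignment.length))


@dataclass
class FoldAssignment:
    """Map from protein-group key (the exact protein sequence) to fold id.

    ``PINNED_TRAIN`` marks groups that must appear in the train side of every
    split because they have a near-duplicate elsewhere in the dataset.
    """

    n_folds: int
    fold_of_group: dict[str, int]

    def test_groups(self, fold: int) -> set[str]:
        return {g for g, f in self.fold_of_group.items() if f == fold}

    def train_groups(self, fold: int) -> set[str]:
        return {g for g, f in self.fold_of_group.items() if f != fold}


def build_folds(
    records,
    n_folds: int = 10,
    pin_threshold: float = 1.5,
    rng: np.random.Generator | None = None,
) -> FoldAssignment:
    """Protein-disjoint folds with near-duplicate pinning.

    ``records`` is any iterable with a ``protein_seq`` attribute (one group
    per distinct sequence).  Every protein whose normalised score with any
    *other* protein exceeds ``pin_threshold`` is pinned to train; the rest are
    shuffled (seeded) and assigned greedily to the currently smallest fold by
    record count.
    """
    rng = rng or np.random.default_rng()
    counts: dict[str, int] = {}
    for r in records:
        counts[r.protein_seq] = counts.get(r.protein_seq, 0) + 1
    proteins = sorted(counts)
    pinned: set[str] = set()
    for i, p in enumerate(proteins):
        for q in proteins[i + 1:]:
            if normalized_alignment_score(p, q).normalized > pin_threshold:
                pinned.add(p)
                pinned.add(q)
    free = [p for p in proteins if p not in pinned]
    if len(free) < n_folds:
        raise ValueError(
            f"need at least {n_folds} unpinned protein groups, have {len(free)}")
    order = rng.permutation(len(free))
    fold_sizes = np.zeros(n_folds, dtype=int)
    assignment: dict[str, int] = {p: PINNED_TRAIN for p in pinned}
    for idx in order:
        p = free[idx]
        fold = int(np.argmin(fold_sizes))
        assignment[p] = fold
        fold_sizes[fold] += counts[p]
    return FoldAssignment(n_folds=n_folds, fold_of_group=assignment)


def audit_leakage(assignment: FoldAssignment, threshold: float = 1.5) -> int:
    """Count test/train protein pairs above the homology threshold (0 = clean)."""
    violations = 0
    groups = list(assignment.fold_of_group)
    for fold in range(assignment.n_folds):
        test = assignment.test_groups(fold)
        train = [g for g in groups if g not in test]
        for t in test:
            for tr in train:
                if normalized_alignment_score(t, tr).normalized > threshold:
                    violations += 1
    return violations


def filter_external_overlap(
    external_proteins: list[str], reference_proteins: list[str], threshold: float = 1.5
) -> list[str]:
    """Drop external proteins with significant homology to any reference."""
    retained = []
    for e in external_proteins:
        if all(normalized_alignment_score(e, r).normalized <= threshold
               for r in reference_proteins):
            retained.append(e)
    return retained


# -------------------------------------------------------------- contact labels
def _chain_kind(residue_names: list[str]) -> str:
    names = set(residue_names)
    if names & _PROTEIN_RESNAMES and not names & _NUCLEIC_RESNAMES:
        return "protein"
    if names & _NUCLEIC_RESNAMES and not names & _PROTEIN_RESNAMES:
        return "nucleic"
    return "other"


def residue_min_distances(structure_path: str | Path) -> np.ndarray:
    """Per protein residue, the minimum heavy-atom distance to any nucleotide.

    The structure must contain strictly one protein chain and one or two
    nucleic-acid chains; anything else is rejected.  Residues with missing
    atoms are measured from the atoms present (warning logged).
    """
    import gemmi

    structure = gemmi.read_structure(str(structure_path))
    model = structure[0]
    protein_chains, nucleic_atoms = [], []
    for chain in model:
        kind = _chain_kind([res.name for res in chain])
        if kind == "protein":
            protein_chains.append(chain)
        elif kind == "nucleic":
            for res in chain:
                for atom in res:
                    if atom.element.name != "H":
                        nucleic_atoms.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if len(protein_chains) != 1:
        raise ValueError(f"expected exactly one protein chain, found {len(protein_chains)}")
    n_nucleic = sum(1 for chain in model if _chain_kind([r.name for r in chain]) == "nucleic")
    if n_nucleic not in (1, 2):
        raise ValueError(f"expected one or two nucleic chains, found {n_nucleic}")
    nuc = np.asarray(nucleic_atoms)
    dists = []
    for res in protein_chains[0]:
        coords = np.asarray([[a.pos.x, a.pos.y, a.pos.z] for a in res if a.element.name != "H"])
        if coords.size == 0:
            logger.warning("residue %s has no heavy atoms; labeled non-contact", res.name)
            dists.append(np.inf)
            continue
        dists.append(float(cdist(coords, nuc).min()))
    return np.asarray(dists)


def label_contacts(structure_path: str | Path, threshold_angstrom: float) -> np.ndarray:
    """Boolean per-residue contact labels at a distance threshold (4/6/8 A)."""
    if threshold_angstrom <= 0:
        raise ValueError("threshold must be positive")
    return residue_min_distances(structure_path) <= threshold_angstrom


def label_contacts_from_distances(min_distances: np.ndarray, threshold_angstrom: float) -> np.ndarray:
    return np.asarray(min_distances) <= threshold_angstrom


# ------------------------------------------------------------------- baselines
def max_random_f1(pos_to_neg_ratio: float) -> float:
    """Best expected F1 attainable by label-independent guessing.

    With prevalence p = r/(1+r), a guesser that predicts positive with rate q
    has precision p and recall q, so expected F1 = 2pq/(p+q), increasing in q;
    the supremum is at q = 1, giving 2p/(1+p).
    """
    r = pos_to_neg_ratio
    if r < 0:
        raise ValueError("ratio must be non-negative")
    p = r / (1.0 + r)
    return 2.0 * p / (1.0 + p)


# --------------------------------------------------------------------- metrics
def metrics(predictions, truths, kind: str) -> float:
    """Scalar evaluation metrics shared across tasks.

    ``pcc`` of a constant vector is undefined and reported as 0.0 with a
    warning (a constant predictor has no linear association to measure).
    """
    pred = np.asarray(predictions, dtype=float)
    true = np.asarray(truths, dtype=float)
    if kind == "pcc":
        if np.std(pred) == 0 or np.std(true) == 0:
            logger.warning("PCC undefined for constant input; reporting 0")
            return 0.0
        return float(np.corrcoef(pred, true)[0, 1])
    if kind == "mae":
        return float(np.abs(pred - true).mean())
    if kind == "spearman":
        return float(spearmanr(pred, true).statistic)
    if kind == "accuracy":
        return float((pred.astype(int) == true.astype(int)).mean())
    if kind == "f1":
        tp = float(((pred > 0.5) & (true > 0.5)).sum())
        fp = float(((pred > 0.5) & (true <= 0.5)).sum())
        fn = float(((pred <= 0.5) & (true > 0.5)).sum())
        if tp == 0:
            if fp == 0 and fn == 0:
                return 1.0
            logger.warning("F1 with no true positives; reporting 0")
            return 0.0
        return 2 * tp / (2 * tp + fp + fn)
    if kind == "mcc":
        y_pred = pred > 0.5
        y_true = true > 0.5
        tp = float((y_pred & y_true).sum())
        tn = float((~y_pred & ~y_true).sum())
        fp = float((y_pred & ~y_true).sum())
        fn = float((~y_pred & y_true).sum())
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if denom == 0:
            logger.warning("MCC undefined; reporting 0")
            return 0.0
        return (tp * tn - fp * fn) / denom
    raise ValueError(f"unknown metric {kind!r}")


def precision_at_L(pred_map: np.ndarray, true_map: np.ndarray,
                   mask: np.ndarray | None = None, top: int | None = None) -> float:
    """Precision of the top-L highest-scoring (masked) pairs of a contact map."""
    pred = np.asarray(pred_map, dtype=float)
    true = np.asarray(true_map, dtype=bool)
    L = pred.shape[0] if top is None else top
    if mask is not None:
        flat_idx = np.flatnonzero(np.asarray(mask, dtype=bool))
    else:
        flat_idx = np.arange(pred.size)
    order = flat_idx[np.argsort(-pred.ravel()[flat_idx])][:L]
    return float(true.ravel()[order].mean())
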