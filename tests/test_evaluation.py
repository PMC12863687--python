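"""Alignment scoring, fold construction, contact labeling, metrics, baselines."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from bioseqlm.evaluation import (AlignmentScore, audit_leakage, build_folds,
                                 filter_external_overlap, label_contacts,
                                 label_contacts_from_distances, max_random_f1,
                                 metrics, normalized_alignment_score,
                                 precision_at_L)
from bioseqlm.heads import ComplexRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_global_score(a, b, gap_open=11, gap_extend=1):
    """Exhaustive enumeration of global alignments (tiny sequences only)."""
    best = -np.inf

    def rec(i, j, score, in_gap_a, in_gap_b):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + BLOSUM62[a[i], b[j]], False, False)
        if i < len(a):
            cost = gap_extend if in_gap_a else gap_open
            rec(i + 1, j, score - cost, True, False)
        if j < len(b):
            cost = gap_extend if in_gap_b else gap_open
            rec(i, j + 1, score - cost, False, True)

    rec(0, 0, 0.0, False, False)
    return best


def random_protein(rng, lo=8, hi=30):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                              size=rng.integers(lo, hi)))


def test_self_alignment_of_homopolymer():
    s = normalized_alignment_score("LLLLLLLLLL", "LLLLLLLLLL")
    assert s.normalized == pytest.approx(4.0)  # BLOSUM62 L/L
    assert s.length == 10


def test_alignment_symmetry():
    rng = np.random.default_rng(0)
    for _ in range(40):
        a, b = random_protein(rng), random_protein(rng)
        assert normalized_alignment_score(a, b).raw == \
            normalized_alignment_score(b, a).raw
        assert normalized_alignment_score(a, b).normalized == \
            normalized_alignment_score(b, a).normalized


def test_alignment_matches_exhaustive_oracle_on_short_sequences():
    rng = np.random.default_rng(1)
    alphabet = list("ACDE")
    for _ in range(40):
        a = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        b = "".join(rng.choice(alphabet, size=rng.integers(1, 7)))
        assert normalized_alignment_score(a, b).raw == \
            pytest.approx(brute_force_global_score(a, b))


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        normalized_alignment_score("", "MKV")


def test_random_composition_self_score_in_blosum_range():
    rng = np.random.default_rng(2)
    scores = [normalized_alignment_score(p, p).normalized
              for p in (random_protein(rng, 20, 40) for _ in range(20))]
    assert 4.0 <= np.mean(scores) <= 11.0


@pytest.fixture(scope="module")
def dissimilar_records():
    rng = np.random.default_rng(3)
    records = []
    for _ in range(20):
        records.append(ComplexRecord(random_protein(rng, 25, 35), ("ACGT",),
                                     dG=-7.0))
    # duplicate records sharing a protein must land in the same group
    records.append(ComplexRecord(records[0].protein_seq, ("ACGTA",), dG=-8.0))
    return records


def test_folds_partition_dissimilar_proteins(dissimilar_records):
    folds = build_folds(dissimilar_records, n_folds=10,
                        rng=np.random.default_rng(0))
    assignment = folds.fold_of_group
    assert len(assignment) == 20
    assert all(f >= 0 for f in assignment.values())  # nothing pinned
    assert {f for f in assignment.values()} == set(range(10))
    # grouping by exact sequence: the duplicated protein has one assignment
    assert dissimilar_records[0].protein_seq in assignment


def test_planted_near_duplicate_is_pinned(dissimilar_records):
    base = dissimilar_records[0].protein_seq
    near = base[:-1] + ("A" if base[-1] != "A" else "C")
    assert normalized_alignment_score(base, near).normalized > 1.5
    records = dissimilar_records + [ComplexRecord(near, ("ACG",), dG=-6.0)]
    folds = build_folds(records, n_folds=10, rng=np.random.default_rng(1))
    from bioseqlm.evaluation import PINNED_TRAIN

    assert folds.fold_of_group[base] == PINNED_TRAIN
    assert folds.fold_of_group[near] == PINNED_TRAIN
    assert audit_leakage(folds) == 0


def test_too_few_groups_rejected(dissimilar_records):
    with pytest.raises(ValueError):
        build_folds(dissimilar_records[:5], n_folds=10)


def test_filter_external_overlap():
    rng = np.random.default_rng(4)
    reference = [random_protein(rng, 20, 30) for _ in range(5)]
    externals = [random_protein(rng, 20, 30) for _ in range(10)] + [reference[0]]
    assert filter_external_overlap([], []) == []
    assert filter_external_overlap(externals, []) == externals
    retained = filter_external_overlap(externals, reference)
    assert reference[0] not in retained
    # decision matches pairwise brute force
    for e in externals:
        keep = all(normalized_alignment_score(e, r).normalized <= 1.5
                   for r in reference)
        assert (e in retained) == keep


def _write_two_atom_structure(tmp_path, distance):
    text = (
        f"ATOM      1 CA   ALA A   1       0.000   0.000   0.000  1.00  0.00"
        f"           C\n"
        f"ATOM      2 P     DA B   1    {distance:8.3f}   0.000   0.000  1.00"
        f"  0.00           P\nEND\n")
    path = tmp_path / "two_atom.pdb"
    path.write_text(text)
    return path


def test_contact_threshold_boundary(tmp_path):
    path = _write_two_atom_structure(tmp_path, 7.9)
    assert label_contacts(path, 8.0).tolist() == [True]
    assert label_contacts(path, 6.0).tolist() == [False]


def test_contact_monotonicity_and_oracle():
    from bioseqlm.synthetic import gen_contact_dataset

    fixtures = gen_contact_dataset(5, protein_length=30, coordinates=True,
                                   seed=9)
    import tempfile
    from pathlib import Path

    for fx in fixtures:
        with tempfile.TemporaryDirectory() as td:
            path = Path(td) / "c.pdb"
            path.write_text(fx.pdb_text)
            l4 = label_contacts(path, 4.0)
            l6 = label_contacts(path, 6.0)
            l8 = label_contacts(path, 8.0)
            assert not (l4 & ~l6).any() and not (l6 & ~l8).any()
            # brute-force oracle: parse ATOM records by fixed columns
            prot_xyz, nuc_xyz = [], []
            for line in fx.pdb_text.splitlines():
                if not line.startswith("ATOM"):
                    continue
                xyz = [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                (prot_xyz if line[21] == "A" else nuc_xyz).append(xyz)
            nuc_xyz = np.asarray(nuc_xyz)
            oracle = np.array([
                min(np.linalg.norm(np.asarray(p) - q) for q in nuc_xyz) <= 8.0
                for p in prot_xyz])
            assert (l8 == oracle).all()


def test_chain_count_violations_rejected(tmp_path):
    bad = tmp_path / "bad.pdb"
    bad.write_text(
        "ATOM      1 P     DA B   1       0.000   0.000   0.000  1.00  0.00"
        "           P\nEND\n")
    with pytest.raises(ValueError):
        label_contacts(bad, 8.0)


def test_label_contacts_from_distances():
    d = np.array([3.0, 7.5, 12.0])
    assert label_contacts_from_distances(d, 8.0).tolist() == [True, True, False]


def test_max_random_f1_values():
    assert round(max_random_f1(0.29), 2) == 0.37
    assert max_random_f1(0.0) == 0.0
    assert max_random_f1(1.0) == pytest.approx(2 / 3)
    with pytest.raises(ValueError):
        max_random_f1(-0.1)


def test_max_random_f1_matches_grid_supremum():
    for r in [0.01, 0.1, 0.29, 0.5, 1.0, 2.0, 10.0]:
        p = r / (1 + r)
        grid = np.linspace(1e-6, 1.0, 20001)
        expected_f1 = 2 * p * grid / (p + grid)  # precision=p, recall=q
        assert max_random_f1(r) == pytest.approx(expected_f1.max(), abs=1e-6)


def test_metric_identities():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    assert metrics(v, v, "pcc") == pytest.approx(1.0)
    assert metrics(v, v, "mae") == 0.0
    assert metrics(-v, v, "pcc") == pytest.approx(-1.0)
    assert metrics(v + 1.0, v, "mae") == pytest.approx(1.0)
    assert metrics(np.ones(4), v, "pcc") == 0.0  # constant -> 0 with warning
    assert metrics(v, v + 0.5, "spearman") == pytest.approx(1.0)


def test_mcc_closed_form():
    # TP=2, FP=1, FN=1, TN=6
    pred = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0], dtype=float)
    true = np.array([1, 1, 0, 1, 0, 0, 0, 0, 0, 0], dtype=float)
    expected = (2 * 6 - 1 * 1) / np.sqrt(3 * 3 * 7 * 7)
    assert metrics(pred, true, "mcc") == pytest.approx(expected)


def test_metrics_agree_with_brute_force_formulas():
    rng = np.random.default_rng(5)
    for _ in range(50):
        pred = rng.random(30)
        true = rng.random(30)
        pcc = np.corrcoef(pred, true)[0, 1]
        assert metrics(pred, true, "pcc") == pytest.approx(pcc)
        assert metrics(pred, true, "mae") == pytest.approx(
            np.mean(np.abs(pred - true)))
        yb = (true > 0.5).astype(float)
        pb = (pred > 0.5).astype(float)
        tp = ((pb == 1) & (yb == 1)).sum()
        fp = ((pb == 1) & (yb == 0)).sum()
        fn = ((pb == 0) & (yb == 1)).sum()
        if tp:
            assert metrics(pred, yb, "f1") == pytest.approx(
                2 * tp / (2 * tp + fp + fn))


def test_precision_at_L_identity():
    pred = np.array([[0.9, 0.1], [0.8, 0.2]])
    true = np.array([[1, 0], [1, 0]], dtype=bool)
    assert precision_at_L(pred, true, top=2) == 1.0
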