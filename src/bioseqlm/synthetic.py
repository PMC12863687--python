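"""Seeded synthetic-data generators with known ground truth.

Three generators give every other module a download-free test surface:

* :func:`gen_gene_protein_pairs` — gene/protein pairs related by the standard
  genetic code, with GT...AG-bounded introns so the gene side is not a trivial
  cipher of the protein, and conserved motifs shared across proteins so masked
  language modeling has learnable statistics;
* :func:`gen_binding_dataset` — protein-nucleic-acid complexes whose binding
  free energy comes from a known position-specific energy model (family
  baseline + per-position mismatch penalties + Gaussian noise), fully
  recoverable from the seed, with matching position-frequency matrices;
* :func:`gen_contact_dataset` — complexes whose contacting residues are a
  deterministic function of a planted sequence motif, optionally realised as
  minimal 3-D coordinates so distance-threshold labeling reproduces the
  planted labels exactly.

Every generator is a pure function of its seed and arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .heads import ComplexRecord
from .specificity import PFM
from .tokenization import NUCLEIC_ALPHABET, PROTEIN_ALPHABET

DNA = "ACGT"

# Standard genetic code (DNA codons), stop codons excluded.
GENETIC_CODE: dict[str, str] = {}
_bases = "TCAG"
_aa = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _a in enumerate(_aa):
    codon = _bases[_i // 16] + _bases[(_i // 4) % 4] + _bases[_i % 4]
    GENETIC_CODE[codon] = _a
CODONS_FOR: dict[str, list[str]] = {}
for _codon, _res in sorted(GENETIC_CODE.items()):
    CODONS_FOR.setdefault(_res, []).append(_codon)
STOP_CODONS = CODONS_FOR.pop("*")


@dataclass
class GeneProteinPair:
    """A gene with exon/intron structure and its translated protein."""

    gene: str
    protein: str
    exons: list[tuple[int, int]]  # half-open exonic intervals of ``gene``

    @property
    def coding_sequence(self) -> str:
        return "".join(self.gene[s:e] for s, e in self.exons)


def gen_gene_protein_pairs(
    n: int,
    protein_length_range: tuple[int, int] = (16, 32),
    intron_rate: float = 0.1,
    n_families: int = 8,
    signature_len: int = 4,
    composition_alpha: float = 0.3,
    seed: int = 0,
) -> list[GeneProteinPair]:
    """Paired corpora for the modality-invariance experiments.

    Each protein carries a conserved N-terminal family signature (one of
    ``n_families``) over a background drawn from a per-pair Dirichlet-biased
    residue composition, so the corpus has learnable statistics — family
    motifs, compositional signatures, length — that are visible on both sides
    of the translation map (composition and signature appear in the gene as
    their codon image).  ``intron_rate`` is the per-codon-boundary probability
    of inserting a GT...AG intron.  With ``intron_rate=0`` the gene is exactly
    the coding sequence plus a stop codon (length ``3 * len(protein) + 3``).
    """
    if n <= 0 or protein_length_range[0] <= 0:
        raise ValueError("need positive counts and lengths")
    if signature_len >= protein_length_range[0]:
        raise ValueError("signature longer than the shortest protein")
    rng = np.random.default_rng(seed)
    signatures = ["".join(rng.choice(list(PROTEIN_ALPHABET), size=signature_len))
                  for _ in range(n_families)]
    pairs = []
    for _ in range(n):
        length = int(rng.integers(protein_length_range[0], protein_length_range[1] + 1))
        comp = rng.dirichlet(np.full(len(PROTEIN_ALPHABET), composition_alpha))
        family = int(rng.integers(n_families))
        protein = signatures[family] + "".join(
            rng.choice(list(PROTEIN_ALPHABET), size=length - signature_len, p=comp))
        gene_parts: list[str] = []
        exons: list[tuple[int, int]] = []
        pos = 0
        exon_start = 0

        def _close_exon():
            nonlocal exon_start
            if pos > exon_start:
                exons.append((exon_start, pos))

        codons = [CODONS_FOR[res][rng.integers(len(CODONS_FOR[res]))] for res in protein]
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
        for i, codon in enumerate(codons):
            gene_parts.append(codon)
            pos += 3
            if i < len(codons) - 1 and rng.random() < intron_rate:
                _close_exon()
                intron = "GT" + "".join(rng.choice(list(DNA),
                                                   size=int(rng.integers(4, 16)))) + "AG"
                gene_parts.append(intron)
                pos += len(intron)
                exon_start = pos
        _close_exon()
        pairs.append(GeneProteinPair("".join(gene_parts), protein, exons))
    return pairs


def translate_cds(cds: str) -> str:
    """Independent codon-table walk used for generator self-checks."""
    protein = []
    for i in range(0, len(cds) - 2, 3):
        res = GENETIC_CODE[cds[i:i + 3]]
        if res == "*":
            break
        protein.append(res)
    return "".join(protein)


# ------------------------------------------------------------- binding dataset
@dataclass
class SyntheticBindingModel:
    """Ground-truth energy model behind :func:`gen_binding_dataset`.

    True DG of (protein of family f, nucleic sequence s) is
    ``baseline_f + sum_w penalty_f[s_w, w] + N(0, sigma)`` kcal/mol, where the
    penalty of the family's consensus base is 0 at every position.
    """

    signatures: list[str]  # N-terminal family signature of each family
    consensus: list[str]
    penalties: list[np.ndarray]  # (4, W) each; row order A,C,G,T
    baselines: list[float]  # kcal/mol
    noise_sigma: float

    def family_of(self, protein_seq: str) -> int:
        for f, sig in enumerate(self.signatures):
            if protein_seq.startswith(sig):
                return f
        raise KeyError("protein does not carry a known family signature")

    def true_energy(self, protein_seq: str, nucleic_seq: str) -> float:
        f = self.family_of(protein_seq)
        pen = self.penalties[f]
        total = self.baselines[f]
        for w, base in enumerate(nucleic_seq):
            total += pen[DNA.index(base), w]
        return float(total)

    def pfm(self, family: int, scale: float = 60.0) -> PFM:
        counts = np.rint(scale * np.exp(-self.penalties[family])).astype(int)
        return PFM(counts=counts, identifier=f"FAM{family}")


def gen_binding_dataset(
    n_families: int = 2,
    proteins_per_family: int = 10,
    seqs_per_protein: int = 16,
    motif_width: int = 8,
    noise_sigma: float = 0.5,
    protein_length: int = 24,
    signature_len: int = 6,
    substitution_rate: float = 0.25,
    planted_near_duplicates: int = 0,
    max_background_similarity: float = 1.4,
    seed: int = 0,
) -> tuple[list[ComplexRecord], SyntheticBindingModel]:
    """Binding dataset with recoverable, interaction-dominated energetics.

    Proteins within a family share an N-terminal signature over otherwise
    random backgrounds (backgrounds are resampled until every protein pair
    stays below ``max_background_similarity`` under the normalised BLOSUM62
    score, so folds are never starved by accidental homology); across
    families the sequences are unrelated.  Families come in pairs with
    *opposing* specificities — family 2f+1's penalty matrix is the column
    complement of family 2f's — and baselines are drawn from a narrow range,
    so the family-averaged nucleic preference is constant: the learnable
    signal is almost entirely the protein-family x nucleic-sequence
    interaction, which an additive (single-omic dual-encoder) predictor
    cannot represent.  Probe sequences are noisy copies of the consensus of a
    *uniformly random* family, independent of the record's protein, so the
    nucleic marginal distribution carries no family information either.

    With ``planted_near_duplicates = k``, k extra proteins are added that
    differ from an existing protein by a single residue (homology far above
    the pinning threshold), to exercise leakage control.
    """
    from .evaluation import normalized_alignment_score

    rng = np.random.default_rng(seed)
    signatures, consensus, penalties, baselines = [], [], [], []
    base_pen = None
    for f in range(n_families):
        signatures.append("".join(rng.choice(list(PROTEIN_ALPHABET), size=signature_len)))
        if f % 2 == 0:
            base_pen = rng.uniform(0.5, 2.5, size=(4, motif_width))
            pen = base_pen.copy()
        else:
            pen = base_pen.max(axis=0, keepdims=True) - base_pen
        pen = pen - pen.min(axis=0, keepdims=True)  # consensus base costs 0
        penalties.append(pen)
        consensus.append("".join(DNA[i] for i in np.argmin(pen, axis=0)))
        baselines.append(float(rng.uniform(-10.0, -8.0)))
    model = SyntheticBindingModel(signatures, consensus, penalties, baselines,
                                  noise_sigma)

    proteins: list[str] = []
    for f in range(n_families):
        for _ in range(proteins_per_family):
            while True:
                background = "".join(rng.choice(list(PROTEIN_ALPHABET),
                                                size=protein_length - signature_len))
                candidate = signatures[f] + background
                if all(normalized_alignment_score(candidate, p).normalized
                       <= max_background_similarity for p in proteins):
                    break
            proteins.append(candidate)
    for i in range(planted_near_duplicates):
        src = proteins[i % len(proteins)]
        pos = int(rng.integers(signature_len, len(src)))
        alt = rng.choice([a for a in PROTEIN_ALPHABET if a != src[pos]])
        proteins.append(src[:pos] + alt + src[pos + 1:])

    records = []
    for prot in proteins:
        for _ in range(seqs_per_protein):
            template = int(rng.integers(n_families))  # independent of protein
            s = list(model.consensus[template])
            for w in range(motif_width):
                if rng.random() < substitution_rate:
                    s[w] = rng.choice([b for b in DNA if b != s[w]])
            seq = "".join(s)
            dg = model.true_energy(prot, seq)
            if noise_sigma > 0:
                dg += float(rng.normal(0.0, noise_sigma))
            records.append(ComplexRecord(prot, (seq,), dG=dg))
    return records, model


# ------------------------------------------------------------- contact dataset
@dataclass
class ContactFixture:
    record: ComplexRecord
    pdb_text: str | None = None


def _minimal_pdb(protein_seq: str, labels: np.ndarray, rng: np.random.Generator) -> str:
    """One CA atom per residue; contacts placed 5 A from a two-atom nucleic
    chain at the origin, non-contacts on a distant line (>= 20 A)."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
        "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
        "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
        "W": "TRP", "Y": "TYR",
    }
    lines = []
    serial = 1

    def atom(name, resname, chain, resnum, x, y, z, element):
        nonlocal serial
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resnum:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}")
        serial += 1

    n_contacts = 0
    for i, (res, lab) in enumerate(zip(protein_seq, labels)):
        if lab:
            theta = 2.0 * np.pi * (n_contacts * 0.37 % 1.0)
            x, y, z = 5.0 * np.cos(theta), 5.0 * np.sin(theta), 0.5 * n_contacts
            n_contacts += 1
        else:
            x, y, z = 20.0 + 10.0 * i, 100.0, 0.0
        atom("CA", three[res], "A", i + 1, x, y, z, "C")
    atom("P", "DA", "B", 1, 0.0, 0.0, 0.0, "P")
    atom("P", "DA", "B", 2, 1.5, 0.0, 0.0, "P")
    lines.append("END")
    return "\n".join(lines) + "\n"


def gen_contact_dataset(
    n: int,
    protein_length: int = 32,
    motif: str = "RKR",
    target_ratio: float = 0.29,
    nucleic_length: int = 12,
    coordinates: bool = False,
    seed: int = 0,
) -> list[ContactFixture]:
    """Contact-labeled complexes driven by a planted binding motif.

    A residue is a contact iff it lies inside one of the planted motif windows
    (the motif itself plus a 0-1 residue jitter on each side).  The number of
    planted copies is set so the expected positive:negative ratio approximates
    ``target_ratio``.  With ``coordinates=True`` each fixture also carries a
    minimal PDB whose 8 A distance labels equal the planted labels.
    """
    rng = np.random.default_rng(seed)
    p = target_ratio / (1.0 + target_ratio)
    span = len(motif) + 1  # expected labeled width incl. jitter
    k = max(1, int(round(p * protein_length / span)))
    fixtures = []
    alphabet = [a for a in PROTEIN_ALPHABET if a not in set(motif)]
    for _ in range(n):
        seq = list(rng.choice(alphabet, size=protein_length))
        labels = np.zeros(protein_length, dtype=bool)
        starts = rng.choice(protein_length - len(motif) + 1, size=k, replace=False)
        for s in sorted(starts):
            seq[s:s + len(motif)] = list(motif)
            lo = max(0, s - int(rng.integers(0, 2)))
            hi = min(protein_length, s + len(motif) + int(rng.integers(0, 2)))
            labels[lo:hi] = True
        protein = "".join(seq)
        nucleic = "".join(rng.choice(list(DNA), size=nucleic_length))
        record = ComplexRecord(protein, (nucleic,), contact_labels=labels)
        pdb = _minimal_pdb(protein, labels, rng) if coordinates else None
        fixtures.append(ContactFixture(record, pdb))
    return fixtures
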