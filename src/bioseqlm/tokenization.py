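"""Modality-disjoint tokenizers for nucleic-acid and protein sequences.

Protein and nucleic-acid sequences are tokenized with *separate* vocabularies
whose id ranges never overlap, so the same literal string (e.g. ``"ACGT"``,
which is both a valid oligonucleotide and a tetrapeptide) maps to different
token ids depending on its modality.  Two tokenizer families are supported:

* byte-pair encoding (BPE), trained by iterative merging of the most frequent
  adjacent symbol pair, with greedy longest-match segmentation at encode time;
* single-character vocabularies (one id per canonical base or residue).

Every encoded sequence carries per-token character spans (0-based, half-open)
that tile the input exactly; all per-residue <-> per-token transforms in the
package rely on that bookkeeping.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NUCLEIC_ALPHABET = "ACGTU"

SPECIAL_NAMES = ("cls", "sep", "mask", "pad")


class Modality(Enum):
    NUCLEIC = "nucleic"
    PROTEIN = "protein"

    @property
    def alphabet(self) -> str:
        return NUCLEIC_ALPHABET if self is Modality.NUCLEIC else PROTEIN_ALPHABET


@dataclass(frozen=True)
class Vocabulary:
    """A piece list over one modality's alphabet plus four special tokens.

    Piece ``i`` has global id ``id_offset + i``; special ids live outside the
    piece range (and outside the partner modality's range when vocabularies are
    trained as a disjoint pair).
    """

    pieces: tuple[str, ...]
    modality: Modality
    id_offset: int
    special_ids: dict[str, int]

    def __post_init__(self):
        alphabet = set(self.modality.alphabet)
        for p in self.pieces:
            if not set(p) <= alphabet:
                raise ValueError(f"piece {p!r} contains characters outside the "
                                 f"{self.modality.value} alphabet")
        piece_range = set(self.id_range)
        for name, sid in self.special_ids.items():
            if sid in piece_range:
                raise ValueError(f"special id {name}={sid} collides with piece range")

    @property
    def size(self) -> int:
        return len(self.pieces)

    @property
    def id_range(self) -> range:
        return range(self.id_offset, self.id_offset + len(self.pieces))

    @property
    def max_id(self) -> int:
        return max(max(self.id_range), *self.special_ids.values())

    def piece_to_id(self, piece: str) -> int:
        return self.id_offset + self.pieces.index(piece)

    def id_to_piece(self, token_id: int) -> str:
        if token_id not in self.id_range:
            raise KeyError(f"id {token_id} outside the {self.modality.value} "
                           f"piece range {self.id_range}")
        return self.pieces[token_id - self.id_offset]

    # ------------------------------------------------------------------- io
    def save(self, path: str | Path) -> None:
        lines = [f"#modality\t{self.modality.value}", f"#id_offset\t{self.id_offset}"]
        lines += [f"#special\t{k}\t{v}" for k, v in self.special_ids.items()]
        lines += list(self.pieces)
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "Vocabulary":
        modality = None
        offset = 0
        specials: dict[str, int] = {}
        pieces: list[str] = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("#modality"):
                modality = Modality(line.split("\t")[1])
            elif line.startswith("#id_offset"):
                offset = int(line.split("\t")[1])
            elif line.startswith("#special"):
                _, k, v = line.split("\t")
                specials[k] = int(v)
            elif line:
                pieces.append(line)
        if modality is None:
            raise ValueError(f"{path}: missing modality header")
        return cls(tuple(pieces), modality, offset, specials)


@dataclass
class TokenizedSequence:
    """Token ids with the half-open character span each token covers."""

    ids: list[int]
    spans: list[tuple[int, int]]
    modality: Modality

    def __post_init__(self):
        if len(self.ids) != len(self.spans):
            raise ValueError("ids and spans must have equal length")
        pos = 0
        for start, end in self.spans:
            if start != pos or end <= start:
                raise ValueError(f"spans must tile the sequence; got {self.spans}")
            pos = end

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_residues(self) -> int:
        return self.spans[-1][1] if self.spans else 0


def validate_sequence(sequence: str, modality: Modality) -> None:
    alphabet = set(modality.alphabet)
    for i, ch in enumerate(sequence):
        if ch not in alphabet:
            raise ValueError(
                f"invalid {modality.value} character {ch!r} at position {i}")


def sample_corpus(sequences: list[str], n_chars: int, rng: np.random.Generator) -> list[str]:
    """Seeded subsample of sequences totalling about ``n_chars`` characters.

    Mirrors training tokenizers on a small character budget rather than the
    full corpus; the budget is a configuration knob.
    """
    order = rng.permutation(len(sequences))
    picked, total = [], 0
    for i in order:
        picked.append(sequences[i])
        total += len(sequences[i])
        if total >= n_chars:
            break
    return picked


def _bpe_merges(corpus: list[str], vocab_size: int, alphabet: str) -> list[str]:
    """Greedy most-frequent-pair merging; ties broken lexicographically."""
    pieces = list(alphabet)
    seqs = [list(s) for s in corpus]
    while len(pieces) < vocab_size:
        counts: Counter[tuple[str, str]] = Counter()
        for s in seqs:
            for a, b in zip(s, s[1:]):
                counts[(a, b)] += 1
        if not counts:
            break
        best = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        merged = best[0] + best[1]
        pieces.append(merged)
        for s in seqs:
            i = 0
            while i < len(s) - 1:
                if s[i] == best[0] and s[i + 1] == best[1]:
                    s[i:i + 2] = [merged]
                else:
                    i += 1
    return pieces


def train_tokenizer(
    corpus_sample: list[str],
    modality: Modality,
    vocab_size: int | None = None,
    algorithm: str = "bpe",
    id_offset: int = 0,
    special_base: int | None = None,
) -> Vocabulary:
    """Train a vocabulary for one modality.

    ``algorithm="single_char"`` ignores ``vocab_size`` and emits one piece per
    canonical symbol.  ``algorithm="bpe"`` grows the piece list to
    ``vocab_size`` by pair merging.  Sequences containing non-canonical
    characters are dropped with a logged warning.  Deterministic given the
    corpus (ties in pair counts are broken lexicographically).
    """
    alphabet = modality.alphabet
    kept = []
    for s in corpus_sample:
        if set(s) <= set(alphabet) and s:
            kept.append(s)
        else:
            logger.warning("rejecting sequence with non-canonical characters: %.20r", s)
    if not kept:
        raise ValueError("no valid sequences in corpus sample")

    if algorithm == "single_char":
        pieces = tuple(alphabet)
    elif algorithm == "bpe":
        if vocab_size is None or vocab_size < len(alphabet):
            raise ValueError(f"vocab_size must be >= alphabet size {len(alphabet)}")
        pieces = tuple(_bpe_merges(kept, vocab_size, alphabet))
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")

    base = special_base if special_base is not None else id_offset + len(pieces)
    specials = {name: base + i for i, name in enumerate(SPECIAL_NAMES)}
    return Vocabulary(pieces, modality, id_offset, specials)


def train_vocabulary_pair(
    nucleic_corpus: list[str],
    protein_corpus: list[str],
    vocab_size: int | None = 2048,
    algorithm: str = "bpe",
) -> tuple[Vocabulary, Vocabulary]:
    """Train the two modality vocabularies with globally disjoint id ranges.

    Layout: nucleic pieces first, protein pieces next, then the two blocks of
    special ids (nucleic cls/sep/mask/pad, protein cls/sep/mask/pad).
    """
    tmp_base = 1 << 30  # placeholder special block, rewritten below
    nuc = train_tokenizer(nucleic_corpus, Modality.NUCLEIC, vocab_size, algorithm,
                          id_offset=0, special_base=tmp_base)
    n_nuc = nuc.size
    size_p = vocab_size if algorithm == "bpe" else None
    prot = train_tokenizer(protein_corpus, Modality.PROTEIN, size_p, algorithm,
                           id_offset=n_nuc, special_base=tmp_base)
    base = n_nuc + prot.size
    nuc_specials = {name: base + i for i, name in enumerate(SPECIAL_NAMES)}
    prot_specials = {name: base + 4 + i for i, name in enumerate(SPECIAL_NAMES)}
    nuc = Vocabulary(nuc.pieces, Modality.NUCLEIC, 0, nuc_specials)
    prot = Vocabulary(prot.pieces, Modality.PROTEIN, n_nuc, prot_specials)
    return nuc, prot


def encode(sequence: str, vocabulary: Vocabulary) -> TokenizedSequence:
    """Greedy longest-match segmentation with exact span bookkeeping."""
    validate_sequence(sequence, vocabulary.modality)
    by_first: dict[str, list[tuple[str, int]]] = {}
    for i, p in enumerate(vocabulary.pieces):
        by_first.setdefault(p[0], []).append((p, vocabulary.id_offset + i))
    for lst in by_first.values():
        lst.sort(key=lambda pi: -len(pi[0]))  # longest first
    ids: list[int] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    n = len(sequence)
    while pos < n:
        for piece, pid in by_first[sequence[pos]]:
            if sequence.startswith(piece, pos):
                ids.append(pid)
                spans.append((pos, pos + len(piece)))
                pos += len(piece)
                break
        else:  # pragma: no cover - single chars always present
            raise ValueError(f"cannot segment at position {pos}")
    return TokenizedSequence(ids, spans, vocabulary.modality)


def decode(tokens: TokenizedSequence | list[int], vocabulary: Vocabulary) -> str:
    """Exact inverse of :func:`encode`; special ids decode to the empty string."""
    ids = tokens.ids if isinstance(tokens, TokenizedSequence) else list(tokens)
    special_set = set(vocabulary.special_ids.values())
    out = []
    for token_id in ids:
        if token_id in special_set:
            continue
        out.append(vocabulary.id_to_piece(token_id))
    return "".join(out)
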