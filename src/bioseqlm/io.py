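"""Readers and writers for the plain-text formats the package exchanges.

FASTA ('>' headers, 60-column wrapping), JASPAR-style PFM text (4 labelled
count rows per record), the tab-separated complex table
(protein_seq, nucleic_seq_1[, nucleic_seq_2][, dG]), and run-configuration
snapshots.  Internally all coordinates are 0-based half-open; energies are
kcal/mol.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .heads import ComplexRecord
from .specificity import BASES, PFM

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------- FASTA
def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(header, sequence) pairs; lowercase input is upcased with a warning."""
    entries: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    text = Path(path).read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header = line[1:]
            chunks = []
        else:
            if line != line.upper():
                logger.warning("upcasing lowercase sequence line in %s", path)
                line = line.upper()
            chunks.append(line)
    if header is not None:
        entries.append((header, "".join(chunks)))
    return entries


def write_fasta(path: str | Path, entries: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in entries:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ------------------------------------------------------------------ JASPAR PFM
def read_pfm_jaspar(path: str | Path) -> list[PFM]:
    """Parse JASPAR-format PFMs: '>' header, then A/C/G/T count rows
    (brackets optional).  Every record must provide all four base rows."""
    records: list[PFM] = []
    identifier = None
    rows: dict[str, list[float]] = {}

    def flush():
        nonlocal rows, identifier
        if identifier is None and not rows:
            return
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise ValueError(f"PFM {identifier!r}: missing base rows {missing}")
        counts = np.asarray([rows[b] for b in BASES])
        records.append(PFM(counts=counts, identifier=identifier or ""))
        rows = {}
        identifier = None

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if rows:
                flush()
            identifier = line[1:].split()[0]
        else:
            base, rest = line[0], line[1:]
            values = [float(v) for v in rest.replace("[", " ").replace("]", " ").split()]
            rows[base.upper()] = values
    flush()
    return records


def write_pfm_jaspar(path: str | Path, pfms: list[PFM]) -> None:
    with open(path, "w") as fh:
        for pfm in pfms:
            fh.write(f">{pfm.identifier}\n")
            for b, row in zip(BASES, pfm.counts):
                fh.write(f"{b} [ " + " ".join(str(int(v)) for v in row) + " ]\n")


# --------------------------------------------------------------- complex table
def read_complex_table(path: str | Path) -> list[ComplexRecord]:
    """TSV of complexes; rows with non-canonical characters are dropped and
    counted in the log.  Columns: protein_seq, nucleic_seq_1[, nucleic_seq_2]
    [, dG]; a trailing numeric field is read as dG."""
    records: list[ComplexRecord] = []
    dropped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        dg = None
        if parts and _is_number(parts[-1]):
            dg = float(parts[-1])
            parts = parts[:-1]
        try:
            protein, nucleics = parts[0], tuple(p for p in parts[1:] if p)
            records.append(ComplexRecord(protein, nucleics, dG=dg))
        except (ValueError, IndexError):
            dropped += 1
    if dropped:
        logger.warning("dropped %d rows with non-canonical or malformed content", dropped)
    return records


def write_complex_table(path: str | Path, records: list[ComplexRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            row = [r.protein_seq, *r.nucleic_seqs]
            if r.dG is not None:
                row.append(f"{r.dG:.6g}")
            fh.write("\t".join(row) + "\n")


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ----------------------------------------------------------------- run configs
@dataclass
class RunConfig:
    """Every tunable the command-line tools accept, with the package defaults.

    Unknown keys in a config file are rejected rather than silently ignored;
    each command writes a snapshot of the effective config into its output
    directory so any run is reproducible from the snapshot alone.
    """

    seed: int = 0
    # tokenizer
    vocab_size: int = 2048
    tokenizer_algorithm: str = "bpe"
    tokenizer_sample_chars: int = 100_000
    # encoder
    width: int = 64
    n_layers: int = 2
    n_heads: int = 4
    context_length: int = 128
    rope_base: float = 10000.0
    # pretraining
    mask_rate: float = 0.15
    batch_rows: int = 8
    pretrain_steps: int = 200
    embedding_lr: float = 0.05
    hidden_lr_base: float = 0.05
    start_end_scale: float = 1e-5
    # fine-tuning
    epochs: int = 64
    batch: int = 256
    lr_head: float = 1e-2
    lr_emb: float = 1e-3
    lr_body_base: float = 1e-4
    # evaluation
    n_folds: int = 10
    pin_threshold: float = 1.5
    contact_threshold: float = 8.0
    # probes
    clip_tau: float = 0.07
    clip_rank: int = 16
    probe_steps: int = 10000
    probe_lr: float = 0.01
    train_frac: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def snapshot(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "config_snapshot.yaml"
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path
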