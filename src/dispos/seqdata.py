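"""Sequence and dataset handling.

Promoter sets are equal-length DNA sequences anchored at the transcription
start site (TSS).  Internally all coordinates are 0-based half-open; the
``tss_offset`` of a dataset converts to the TSS-relative coordinates used in
reports (e.g. an offset of -500 means position 0 is 500 bp upstream of the
TSS and the last position is -1).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TySequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
#: letter -> integer code used throughout the package
LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

FOREGROUND = 1
BACKGROUND = 0


class ValidationError(ValueError):
    """Raised when sequences or datasets violate an invariant."""


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over the strict {A,C,G,T} alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        bad = _first_invalid(self.residues)
        if bad is not None:
            raise ValidationError(
                f"sequence {self.id!r} has non-ACGT residue "
                f"{self.residues[bad]!r} at offset {bad}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def encode(self) -> np.ndarray:
        """Integer codes (A=0, C=1, G=2, T=3) as an int8 array."""
        return encode(self.residues)


def _first_invalid(residues: str) -> int | None:
    for i, c in enumerate(residues):
        if c not in LETTER_INDEX:
            return i
    return None


def encode(residues: str) -> np.ndarray:
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for c, i in LETTER_INDEX.items():
        out[arr == ord(c)] = i
    if (out < 0).any():
        raise ValidationError("non-ACGT residue in sequence")
    return out


def decode(codes: Iterable[int]) -> str:
    return "".join(ALPHABET[i] for i in codes)


def reverse_complement(s: str) -> str:
    """Reverse complement of an {A,C,G,T} string (an involution)."""
    if _first_invalid(s) is not None:
        raise ValidationError(f"non-ACGT residue in {s!r}")
    return s.translate(_COMPLEMENT)[::-1]


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path, strict: bool = True) -> list[Sequence]:
    """Read a (possibly gzipped) FASTA file into :class:`Sequence` records.

    Residues are uppercased and multi-line records concatenated.  In strict
    mode any residue outside {A,C,G,T} raises :class:`ValidationError` naming
    the record and offset; in lenient mode the offending record is dropped
    with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    out: list[Sequence] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            residues = str(rec.seq).upper()
            if not rec.id:
                raise ValidationError(f"record without id in {path}")
            bad = _first_invalid(residues)
            if bad is not None:
                if strict:
                    raise ValidationError(
                        f"record {rec.id!r} in {path} has non-ACGT residue "
                        f"{residues[bad]!r} at offset {bad}"
                    )
                logger.warning(
                    "dropping record %r (non-ACGT residue at offset %d)",
                    rec.id, bad,
                )
                continue
            out.append(Sequence(id=rec.id, residues=residues))
    return out


def write_fasta(path: str | Path, seqs: Iterable[Sequence]) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class LabeledDataset:
    """Equal-length sequences with foreground/background class labels.

    The equal-length requirement is structural: the positional prior of the
    motif model is a distribution over absolute start positions, so every
    sequence must live on the same coordinate axis.
    """

    sequences: list[Sequence]
    labels: np.ndarray  # 1 = foreground, 0 = background
    tss_offset: int = -500
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if len(self.sequences) != len(self.labels):
            raise ValidationError("sequences and labels differ in length")
        if len(self.sequences) < 1:
            raise ValidationError("dataset must contain at least one sequence")
        L = len(self.sequences[0])
        bad = [s.id for s in self.sequences if len(s) != L]
        if bad:
            raise ValidationError(
                f"all sequences must share one length ({L} bp); offending ids: "
                + ", ".join(bad[:10])
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n(self) -> int:
        return len(self.sequences)

    def encoded(self) -> np.ndarray:
        """(N, L) int8 matrix of letter codes, cached."""
        if self._encoded is None:
            self._encoded = np.stack([s.encode() for s in self.sequences])
        return self._encoded

    def subset(self, label: int) -> "LabeledDataset":
        idx = np.flatnonzero(self.labels == label)
        return LabeledDataset(
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            tss_offset=self.tss_offset,
        )

    def foreground(self) -> list[Sequence]:
        return [s for s, y in zip(self.sequences, self.labels) if y == FOREGROUND]

    def background(self) -> list[Sequence]:
        return [s for s, y in zip(self.sequences, self.labels) if y == BACKGROUND]

    def to_tss(self, internal_pos: int) -> int:
        """Convert an internal 0-based position to a TSS-relative coordinate."""
        return internal_pos + self.tss_offset

    def from_tss(self, tss_pos: int) -> int:
        return tss_pos - self.tss_offset


def build_dataset(
    fg: TySequence[Sequence],
    bg: TySequence[Sequence],
    tss_offset: int = -500,
) -> LabeledDataset:
    """Assemble a labeled dataset from foreground and background sequences.

    Both classes must be non-empty and all sequences must share one length
    (checked eagerly).
    """
    if not fg or not bg:
        raise ValidationError("both foreground and background must be non-empty")
    seqs = list(fg) + list(bg)
    labels = np.concatenate(
        [np.ones(len(fg), dtype=np.int8), np.zeros(len(bg), dtype=np.int8)]
    )
    return LabeledDataset(sequences=seqs, labels=labels, tss_offset=tss_offset)


def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read BED6-style intervals keyed by sequence id.

    The chrom column carries the sequence id; returns 0-based half-open
    (start, end, strand) tuples per id.  Score and name columns are ignored
    on input.
    """
    out: dict[str, list[tuple[int, int, str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            strand = parts[5] if len(parts) >= 6 else "+"
            if end <= start:
                raise ValidationError(f"{path}:{lineno}: empty or inverted interval")
            out.setdefault(chrom, []).append((start, end, strand))
    return out


def write_bed_intervals(
    path: str | Path,
    rows: Iterable[tuple[str, int, int, str, float, str]],
) -> None:
    """Write (chrom, start, end, name, score, strand) rows as BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
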