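"""Sequence and annotation I/O.

Reads FASTA sequences and interval annotations, normalizes both to a single
internal convention, and applies the minimum-length filter used before any
entropy computation.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (BED-style).  Annotation
sources declare their convention at read time:

* ``bed0half`` — BED files, already 0-based half-open; stored unchanged.
* ``one_inclusive`` — 1-based inclusive coordinate tables as printed in the
  genomics literature (``3770 – 3826 bp``); a pair ``(a, b)`` maps to
  ``(a - 1, b)``.

Strand is ignored throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "NucleotideSequence",
    "GenomicInterval",
    "AnnotationSet",
    "KNOWN_LABELS",
    "normalize_residues",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "filter_min_length",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
]

#: Element classes with first-class meaning; anything else becomes "other".
KNOWN_LABELS = frozenset({"exon", "intron", "promoter", "other"})

_CANONICAL = frozenset("ACGT")


def normalize_residues(raw: str) -> str:
    """Normalize a raw residue string to the {A,C,G,T,N} alphabet.

    Lowercase is upcased, U (RNA) maps to T, and every other IUPAC
    ambiguity code (R, Y, S, W, ...) collapses to N.
    """
    out = []
    for ch in raw.upper():
        if ch == "U":
            ch = "T"
        if ch not in _CANONICAL:
            ch = "N"
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class NucleotideSequence:
    """A named DNA sequence over the alphabet {A, C, G, T, N}."""

    identifier: str
    residues: str

    def __post_init__(self) -> None:
        bad = set(self.residues) - (_CANONICAL | {"N"})
        if bad:
            raise ValueError(
                f"sequence {self.identifier!r} contains non-normalized "
                f"characters {sorted(bad)}; use normalize_residues()"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.residues)

    @classmethod
    def from_raw(cls, identifier: str, raw: str) -> "NucleotideSequence":
        return cls(identifier, normalize_residues(raw))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A labeled interval, 0-based half-open, on a named sequence."""

    sequence_id: str
    start: int
    end: int
    label: str = "other"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.sequence_id!r}: need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_one_inclusive(self) -> tuple[int, int]:
        """Back-convert to a 1-based inclusive (start, end) pair."""
        return self.start + 1, self.end


@dataclass
class AnnotationSet:
    """A collection of labeled intervals stored 0-based half-open.

    Same-label intervals on the same sequence are merged on construction so
    that per-base truth labels are single-valued.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    source_convention: str = "bed0half"

    def __post_init__(self) -> None:
        self.intervals = _merge_same_label(self.intervals)

    def with_label(self, label: str) -> list[GenomicInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    def total_length(self, label: str) -> int:
        return sum(iv.length for iv in self.with_label(label))

    def label_mask(
        self, label: str, sequence_id: str, region: GenomicInterval
    ) -> np.ndarray:
        """Boolean per-base mask for ``label`` within ``region``."""
        mask = np.zeros(region.length, dtype=bool)
        for iv in self.intervals:
            if iv.label != label or iv.sequence_id != sequence_id:
                continue
            lo = max(iv.start, region.start) - region.start
            hi = min(iv.end, region.end) - region.start
            if lo < hi:
                mask[lo:hi] = True
        return mask


def _merge_same_label(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    by_key: dict[tuple[str, str], list[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.sequence_id, iv.label), []).append(iv)
    merged: list[GenomicInterval] = []
    for (seq_id, label), ivs in by_key.items():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or adjacency within label
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(seq_id, cur_start, cur_end, label))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(seq_id, cur_start, cur_end, label))
    merged.sort()
    return merged


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a FASTA file into normalized :class:`NucleotideSequence` records.

    Raises ``ValueError`` for an empty file or for a file whose first
    non-blank line is not a FASTA header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"{path}: line {lineno} is not a FASTA header; "
                        "expected a line starting with '>'"
                    )
                break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records = [
        NucleotideSequence.from_raw(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(seqs: Sequence[NucleotideSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.identifier}\n")
            for i in range(0, s.length, width):
                fh.write(s.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _resolve_label(token: str) -> str:
    label = token.lower()
    if label not in KNOWN_LABELS:
        warnings.warn(f"unknown element label {token!r}; using 'other'", stacklevel=3)
        label = "other"
    return label


def read_annotations(
    path: str | Path,
    convention: str,
    default_sequence_id: str = "seq",
    default_label: str = "other",
) -> AnnotationSet:
    """Read interval annotations and normalize to 0-based half-open.

    ``convention`` is ``"bed0half"`` for 4-column BED or ``"one_inclusive"``
    for whitespace/dash-delimited 1-based inclusive tables.  A one-inclusive
    line may read ``3770 – 3826 bp exon`` or ``chr1 3770 3826 exon``; dash
    separators and a trailing ``bp`` unit are tolerated.
    """
    path = Path(path)
    if convention not in ("bed0half", "one_inclusive"):
        raise ValueError(f"unknown coordinate convention {convention!r}")

    intervals: list[GenomicInterval] = []
    if convention == "bed0half":
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
            dtype={"chrom": str, "start": int, "end": int, "name": str},
        )
        for row in df.itertuples(index=False):
            label = _resolve_label(row.name) if isinstance(row.name, str) else default_label
            intervals.append(GenomicInterval(row.chrom, row.start, row.end, label))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tokens = [
                    t for t in line.replace("–", " ").replace("-", " ").split()
                    if t.lower() != "bp"
                ]
                seq_id = default_sequence_id
                if tokens and not tokens[0].lstrip("+").isdigit():
                    seq_id = tokens.pop(0)
                label = default_label
                if tokens and not tokens[-1].lstrip("+").isdigit():
                    label = _resolve_label(tokens.pop())
                if len(tokens) != 2:
                    raise ValueError(
                        f"{path}: line {lineno}: expected a start/end pair, got {line!r}"
                    )
                a, b = int(tokens[0]), int(tokens[1])
                start, end = a - 1, b  # 1-based inclusive -> 0-based half-open
                if not (0 <= start < end):
                    raise ValueError(
                        f"{path}: line {lineno}: invalid 1-based interval {a}-{b}"
                    )
                intervals.append(GenomicInterval(seq_id, start, end, label))
    return AnnotationSet(intervals, source_convention=convention)


def filter_min_length(
    seqs: Iterable[NucleotideSequence], min_len: int
) -> list[NucleotideSequence]:
    """Keep sequences with length >= ``min_len``, preserving order.

    The default analysis threshold is 200 bp: shorter fragments carry too
    few subword windows for a stable entropy estimate.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    return [s for s in seqs if s.length >= min_len]


# ---------------------------------------------------------------------------
# Track output
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable[GenomicInterval], path: str | Path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for iv in intervals:
            fh.write(f"{iv.sequence_id}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def write_bedgraph(
    scores: np.ndarray, sequence_id: str, path: str | Path, header: str | None = None
) -> None:
    """Write a per-base score vector as 4-column bedGraph.

    Consecutive equal scores collapse to one row (run-length encoding),
    0-based half-open as the format requires.
    """
    scores = np.asarray(scores, dtype=float)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        run_start = 0
        for i in range(1, len(scores) + 1):
            if i == len(scores) or scores[i] != scores[run_start]:
                fh.write(f"{sequence_id}\t{run_start}\t{i}\t{scores[run_start]:.6g}\n")
                run_start = i


def read_bedgraph(path: str | Path) -> tuple[str, np.ndarray]:
    """Expand a single-sequence bedGraph back to a per-base vector."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "score"],
    )
    if df.empty:
        raise ValueError(f"{path}: empty bedGraph")
    seq_id = df["chrom"].iloc[0]
    values = np.empty(int(df["end"].max()), dtype=float)
    values[:] = np.nan
    for row in df.itertuples(index=False):
        values[row.start : row.end] = row.score
    return seq_id, values
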