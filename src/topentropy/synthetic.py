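"""Synthetic sequences with known complexity structure.

Generators for the sequence classes the entropy method is sensitive to:
i.i.d. background with a chosen GC content, short-motif repeat segments
(a low-complexity surrogate for conserved/repetitive elements such as
exons), homopolymers (entropy exactly 0), and de Bruijn words (entropy
exactly 1).  :func:`build_benchmark` embeds repeat segments at known
coordinates in background sequence, yielding a FASTA-ready sequence plus
a BED-ready exon/intron truth set, so the whole pipeline is testable
without any genome download.

The default benchmark layout mirrors the 7,001 bp region (positions
3500–10500) of GenBank entry AJ229040 used as the method's single-gene
benchmark: six exon-length segments of 57, 18, 60, 279, 94 and 180 bp at
the annotated offsets.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_io import (
    AnnotationSet,
    GenomicInterval,
    NucleotideSequence,
    write_bed,
    write_fasta,
)

__all__ = [
    "SyntheticSpec",
    "AJ_BENCHMARK_SEGMENTS",
    "AJ_BENCHMARK_LENGTH",
    "random_sequence",
    "repeat_segment",
    "homopolymer",
    "de_bruijn_sequence",
    "build_benchmark",
    "aj_benchmark_spec",
]

_ALPHABET = np.array(list("ACGT"))

#: Exon-length segments of the AJ229040 single-gene benchmark, 0-based
#: half-open, relative to region start 3500 (1-based genomic coordinates
#: 3770–3826, 4584–4601, 4671–4730, 4999–5277, 5730–5823, 6719–6898).
AJ_BENCHMARK_SEGMENTS: tuple[tuple[int, int], ...] = (
    (270, 327),
    (1084, 1102),
    (1171, 1231),
    (1499, 1778),
    (2230, 2324),
    (3219, 3399),
)
AJ_BENCHMARK_LENGTH = 7001


@dataclass(frozen=True)
class SyntheticSpec:
    """Layout of a benchmark: background length, repeat segments, seed."""

    length: int
    segment_intervals: tuple[tuple[int, int], ...] = ()
    motif_length: int = 4
    gc_content: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.motif_length < 1:
            raise ValueError("motif_length must be >= 1")
        prev_end = -1
        for start, end in sorted(self.segment_intervals):
            if not (0 <= start < end <= self.length):
                raise ValueError(f"segment ({start}, {end}) outside [0, {self.length})")
            if start < prev_end:
                raise ValueError("segments must be pairwise disjoint")
            prev_end = end


def random_sequence(
    length: int, gc_content: float = 0.5, seed: int | np.random.Generator = 0,
    identifier: str = "random",
) -> NucleotideSequence:
    """I.i.d. sequence with P(G) = P(C) = gc/2 and P(A) = P(T) = (1−gc)/2."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 < gc_content < 1.0:
        raise ValueError(f"gc_content {gc_content} outside (0, 1)")
    rng = np.random.default_rng(seed)
    at, gc = (1 - gc_content) / 2, gc_content / 2
    draws = rng.choice(4, size=length, p=[at, gc, gc, at])
    return NucleotideSequence(identifier, "".join(_ALPHABET[draws]))


def repeat_segment(
    length: int, motif_length: int = 4, seed: int | np.random.Generator = 0,
    identifier: str = "repeat",
) -> NucleotideSequence:
    """A random motif tiled to ``length`` — a low-complexity segment.

    Any window of such a segment holds at most ``motif_length`` distinct
    subwords of each length, so its topological entropy is far below that
    of an i.i.d. sequence.
    """
    if motif_length > length:
        raise ValueError("motif_length must be <= length")
    rng = np.random.default_rng(seed)
    motif = "".join(_ALPHABET[rng.integers(0, 4, size=motif_length)])
    tiled = (motif * (length // motif_length + 1))[:length]
    return NucleotideSequence(identifier, tiled)


def homopolymer(length: int, base: str = "A", identifier: str = "homopolymer") -> NucleotideSequence:
    return NucleotideSequence(identifier, base * length)


def de_bruijn_sequence(order: int, identifier: str = "debruijn") -> NucleotideSequence:
    """A linearized de Bruijn word containing every ``order``-mer exactly once.

    Built by the standard Lyndon-word concatenation; the cyclic word of
    length 4^order is linearized by appending its first order−1 symbols,
    so all 4^order subwords of length ``order`` appear.  Its topological
    entropy is exactly 1.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    k = 4
    a = [0] * k * order
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > order:
            if order % p == 0:
                seq.extend(a[1 : p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    cyc = "".join(_ALPHABET[seq])
    return NucleotideSequence(identifier, cyc + cyc[: order - 1])


def build_benchmark(
    spec: SyntheticSpec,
    fasta_path: str | Path | None = None,
    bed_path: str | Path | None = None,
    identifier: str = "benchmark",
) -> tuple[NucleotideSequence, AnnotationSet]:
    """Background sequence with repeat segments at known coordinates.

    Segments are labeled "exon" in the returned truth set; the complement
    is labeled "intron".  Each segment gets its own independently drawn
    motif.  FASTA/BED files are written when paths are given.
    """
    rng = np.random.default_rng(spec.seed)
    background = random_sequence(spec.length, spec.gc_content, rng, identifier)
    residues = list(background.residues)
    intervals = []
    for start, end in sorted(spec.segment_intervals):
        seg = repeat_segment(end - start, spec.motif_length, rng)
        residues[start:end] = seg.residues
        intervals.append(GenomicInterval(identifier, start, end, "exon"))
    # intron = complement of the segments
    prev = 0
    for start, end in sorted(spec.segment_intervals) + [(spec.length, spec.length)]:
        if prev < start:
            intervals.append(GenomicInterval(identifier, prev, start, "intron"))
        prev = end
    seq = NucleotideSequence(identifier, "".join(residues))
    truth = AnnotationSet(intervals, source_convention="bed0half")
    if fasta_path is not None:
        write_fasta([seq], fasta_path)
    if bed_path is not None:
        write_bed(truth.intervals, bed_path)
    return seq, truth


def aj_benchmark_spec(seed: int = 0, motif_length: int = 4, gc_content: float = 0.5) -> SyntheticSpec:
    """The default benchmark layout (six exon-length segments in 7,001 bp)."""
    return SyntheticSpec(
        length=AJ_BENCHMARK_LENGTH,
        segment_intervals=AJ_BENCHMARK_SEGMENTS,
        motif_length=motif_length,
        gc_content=gc_content,
        seed=seed,
    )
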