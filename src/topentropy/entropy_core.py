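"""Topological entropy of finite DNA sequences.

The topological entropy of a finite word ω over {A,C,G,T} is

    H_top(ω) = log4(p_ω(n_ω)) / n_ω

where n_ω is the largest subword length n with 4^n + n − 1 ≤ |ω|, and
p_ω(n) counts the *distinct* length-n subwords in the first 4^n + n − 1
bases of ω.  The prefix truncation makes the count comparable across
sequence lengths: a prefix of exactly 4^n + n − 1 bases holds 4^n sliding
windows, so a maximally complex sequence (a de Bruijn word) attains
p = 4^n and H = 1, while a homopolymer attains p = 1 and H = 0.

The generalized form averages the per-length terms over the k largest
admissible subword lengths,

    H_k(ω) = (1/k) · Σ_{i = n_ω−k+1}^{n_ω}  log4(p_ω(i)) / i,

with p_ω(i) counted over the whole sequence.

The *modified* variants remove low-frequency subwords from the census
before counting distinct subwords, which emphasizes repetition structure:
a subword seen fewer times than expected under a uniform background
contributes noise rather than signal.  Two filter rules are provided (see
:func:`apply_frequency_filter`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .sequence_io import NucleotideSequence

__all__ = [
    "FILTER_EXPECTED_COUNT",
    "FILTER_LITERAL_RELATIVE",
    "SubwordCensus",
    "compute_n_omega",
    "subword_census",
    "apply_frequency_filter",
    "topological_entropy",
    "generalized_topological_entropy",
    "modified_topological_entropy",
    "modified_generalized_topological_entropy",
]

#: Drop length-n subwords occurring fewer than |ω| / 4^n times — the
#: expected count of each subword under an i.i.d. uniform background.
FILTER_EXPECTED_COUNT = "expected_count"
#: Literal reading of the published criterion: drop subwords whose relative
#: frequency (count / scanned windows) is below 4^{n_ω} / |ω|.
FILTER_LITERAL_RELATIVE = "literal_relative"

_FILTER_RULES = (FILTER_EXPECTED_COUNT, FILTER_LITERAL_RELATIVE)


@dataclass(frozen=True)
class SubwordCensus:
    """Occurrence counts of all length-n subwords of a sequence.

    ``scanned_window_count`` is the number of valid (N-free) length-n
    windows scanned; the counts always sum to it.
    """

    subword_length: int
    counts: dict[str, int]
    scanned_window_count: int
    prefix_truncated: bool

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.scanned_window_count:
            raise ValueError("census counts do not sum to scanned_window_count")

    @property
    def distinct(self) -> int:
        return len(self.counts)


def compute_n_omega(length: int) -> int:
    """Largest subword length n with 4^n + n − 1 ≤ ``length``."""
    if length < 4:
        raise ValueError(f"sequence too short for entropy: {length} < 4 bp")
    n = 1
    while 4 ** (n + 1) + n <= length:
        n += 1
    return n


def subword_census(
    seq: NucleotideSequence | str, n: int, prefix_truncate: bool = False
) -> SubwordCensus:
    """Count all length-``n`` subwords of ``seq`` by sliding a window.

    With ``prefix_truncate`` the scan covers only the first 4^n + n − 1
    bases (the prefix the topological-entropy definition prescribes).
    Windows containing N are skipped entirely.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    if n < 1:
        raise ValueError("subword length must be >= 1")
    if n > len(residues):
        raise ValueError(f"subword length {n} exceeds sequence length {len(residues)}")
    if prefix_truncate:
        prefix_len = 4**n + n - 1
        if len(residues) < prefix_len:
            raise ValueError(
                f"sequence length {len(residues)} < {prefix_len} required for "
                f"prefix-truncated census at n={n}"
            )
        residues = residues[:prefix_len]
    counts: dict[str, int] = {}
    scanned = 0
    for i in range(len(residues) - n + 1):
        word = residues[i : i + n]
        if "N" in word:
            continue
        counts[word] = counts.get(word, 0) + 1
        scanned += 1
    return SubwordCensus(n, counts, scanned, prefix_truncate)


def apply_frequency_filter(
    census: SubwordCensus, seq_length: int, rule: str = FILTER_EXPECTED_COUNT
) -> SubwordCensus:
    """Remove low-frequency subwords from a census.

    ``expected_count`` drops subwords with count < seq_length / 4^n, the
    expected occurrence count of any fixed length-n word in a uniform
    i.i.d. sequence of that length.  ``literal_relative`` drops subwords
    whose relative frequency is below 4^{n_ω} / seq_length, with n_ω
    derived from ``seq_length``.
    """
    if rule not in _FILTER_RULES:
        raise ValueError(f"unknown filter rule {rule!r}; expected one of {_FILTER_RULES}")
    n = census.subword_length
    if rule == FILTER_EXPECTED_COUNT:
        threshold = seq_length / 4**n
        kept = {w: c for w, c in census.counts.items() if c >= threshold}
    else:
        threshold = 4 ** compute_n_omega(seq_length) / seq_length
        scanned = max(census.scanned_window_count, 1)
        kept = {
            w: c for w, c in census.counts.items() if c / scanned >= threshold
        }
    return SubwordCensus(
        n, kept, sum(kept.values()), census.prefix_truncated
    )


def _log4(x: float) -> float:
    return math.log(x) / math.log(4.0)


def _distinct_count(
    seq: NucleotideSequence | str,
    n: int,
    prefix_truncate: bool,
    filtered: bool,
    filter_rule: str,
) -> int:
    census = subword_census(seq, n, prefix_truncate=prefix_truncate)
    if census.scanned_window_count == 0:
        raise ValueError(
            f"entropy undefined: no valid (N-free) length-{n} window in sequence"
        )
    if filtered:
        # The threshold refers to the region the census actually scanned:
        # the truncated prefix for the topological form, the whole sequence
        # otherwise.  Mixing the full length with a prefix census would
        # over-prune short prefixes.
        length = len(seq.residues if isinstance(seq, NucleotideSequence) else seq)
        if prefix_truncate:
            length = min(length, 4**n + n - 1)
        census = apply_frequency_filter(census, length, rule=filter_rule)
    # An emptied census means no subword clears the repetition filter;
    # p is floored at 1 so the term contributes 0.
    return max(census.distinct, 1)


def topological_entropy(
    seq: NucleotideSequence | str,
    *,
    filtered: bool = False,
    filter_rule: str = FILTER_EXPECTED_COUNT,
) -> float:
    """Topological entropy of ``seq``; a value in [0, 1].

    0 marks a perfectly repetitive sequence (homopolymer), 1 a maximally
    complex one in which every admissible subword occurs.
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    n = compute_n_omega(len(residues))
    p = _distinct_count(seq, n, True, filtered, filter_rule)
    return _log4(p) / n


def generalized_topological_entropy(
    seq: NucleotideSequence | str,
    k: int,
    *,
    filtered: bool = False,
    filter_rule: str = FILTER_EXPECTED_COUNT,
) -> float:
    """Mean of the top-``k`` per-length entropy terms; a value in [0, 1].

    ``k`` = 1 reduces to the single term at n_ω (but with subwords counted
    over the whole sequence rather than the truncated prefix).
    """
    residues = seq.residues if isinstance(seq, NucleotideSequence) else seq
    n_omega = compute_n_omega(len(residues))
    if not 1 <= k <= n_omega:
        raise ValueError(f"averaging depth k={k} outside [1, n_omega={n_omega}]")
    total = 0.0
    for i in range(n_omega - k + 1, n_omega + 1):
        p = _distinct_count(seq, i, False, filtered, filter_rule)
        total += _log4(p) / i
    return total / k


def modified_topological_entropy(
    seq: NucleotideSequence | str, filter_rule: str = FILTER_EXPECTED_COUNT
) -> float:
    """Topological entropy with the low-frequency subword filter applied."""
    return topological_entropy(seq, filtered=True, filter_rule=filter_rule)


def modified_generalized_topological_entropy(
    seq: NucleotideSequence | str, k: int, filter_rule: str = FILTER_EXPECTED_COUNT
) -> float:
    """Generalized topological entropy with the low-frequency filter applied."""
    return generalized_topological_entropy(seq, k, filtered=True, filter_rule=filter_rule)
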