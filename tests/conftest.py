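"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive every quantity by the
most naive route available (explicit substring scans, O(n²) pairwise
concordance, direct rank-formula evaluation) so that they stay
independent of the implementation paths they check.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pytest

import topentropy as tp


# ---------------------------------------------------------------------------
# naive entropy oracles
# ---------------------------------------------------------------------------

def naive_census(residues: str, n: int, prefix_truncate: bool = False) -> Counter:
    """Nested-loop subword count, skipping windows containing N."""
    if prefix_truncate:
        residues = residues[: 4**n + n - 1]
    counts: Counter = Counter()
    for i in range(len(residues) - n + 1):
        w = residues[i : i + n]
        if "N" not in w:
            counts[w] += 1
    return counts


def naive_distinct(
    residues: str, n: int, prefix_truncate: bool = False, filtered: bool = False
) -> int:
    counts = naive_census(residues, n, prefix_truncate)
    if filtered:
        region = residues[: 4**n + n - 1] if prefix_truncate else residues
        threshold = len(region) / 4**n
        counts = {w: c for w, c in counts.items() if c >= threshold}
    return max(len(counts), 1)


def naive_topological(residues: str, filtered: bool = False) -> float:
    n = tp.compute_n_omega(len(residues))
    return math.log(naive_distinct(residues, n, True, filtered), 4) / n


def naive_generalized(residues: str, k: int, filtered: bool = False) -> float:
    n = tp.compute_n_omega(len(residues))
    return (
        sum(
            math.log(naive_distinct(residues, i, False, filtered), 4) / i
            for i in range(n - k + 1, n + 1)
        )
        / k
    )


def naive_window_entropy(window_residues: str, k: int, filtered: bool) -> float:
    """Entropy of one explicit window at explicit subword length k."""
    counts = naive_census(window_residues, k)
    if filtered:
        threshold = len(window_residues) / 4**k
        counts = {w: c for w, c in counts.items() if c >= threshold}
    return math.log(max(len(counts), 1), 4) / k


# ---------------------------------------------------------------------------
# classifier / statistics oracles
# ---------------------------------------------------------------------------

def pairwise_auc(scores, labels) -> float:
    """O(n²) Mann–Whitney concordance count; ties contribute 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def direct_kruskal_h(groups) -> tuple[float, float]:
    """H and the tie correction from an explicit rank-and-sum evaluation."""
    pooled = sorted(x for g in groups for x in g)
    N = len(pooled)
    rank_of: dict[float, float] = {}
    for value in set(pooled):
        positions = [i + 1 for i, v in enumerate(pooled) if v == value]
        rank_of[value] = sum(positions) / len(positions)
    h = 0.0
    for g in groups:
        r = sum(rank_of[x] for x in g)
        h += r * r / len(g)
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    tie_sizes = Counter(pooled).values()
    correction = 1.0 - sum(t**3 - t for t in tie_sizes) / (N**3 - N)
    return h / correction, correction


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fasta_file(tmp_path):
    """Write a small FASTA file and return its path factory."""

    def _write(records: dict[str, str], name: str = "seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for ident, residues in records.items():
                fh.write(f">{ident}\n{residues}\n")
        return path

    return _write


# The six published exon intervals of the AJ229040 benchmark region,
# 1-based inclusive, as printed.
AJ_EXON_ROWS_ONE_INCLUSIVE = [
    (3770, 3826),
    (4584, 4601),
    (4671, 4730),
    (4999, 5277),
    (5730, 5823),
    (6719, 6898),
]
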