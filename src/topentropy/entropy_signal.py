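"""Sliding-window entropy profiles and SVD position scores.

A sequence is digitized by sliding a fixed window (default 100 bp) along
it and computing, for each subword length k in a small set (default
2..6), the windowed topological entropy log4(p)/k, where p is the number
of distinct k-mers in the window — optionally after the low-frequency
repetition filter.  Stacking the k rows yields a K×L feature matrix A
(modes × positions); each base thus carries a 1×K entropy vector.

The per-base score is read off a low-rank SVD reconstruction of A,

    A = U S Vᵀ  ≈  U_r S_r V_rᵀ,

as the column mean of the rank-r reconstruction (r = 1 by default).  The
entropy rows for different k are strongly correlated, so the leading
singular direction captures their shared complexity signal while
suppressing per-k noise.

Windows are centered on each base and clamped at the sequence ends so
every base receives a full-size window.  Windows with no valid (N-free)
k-mer produce a missing value, filled by nearest-neighbor imputation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .entropy_core import (
    FILTER_EXPECTED_COUNT,
    FILTER_LITERAL_RELATIVE,
    compute_n_omega,
)
from .sequence_io import NucleotideSequence

__all__ = [
    "EntropyProfile",
    "SVDResult",
    "PositionScore",
    "window_entropy_profile",
    "impute_missing",
    "svd_decompose",
    "svd_position_score",
]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}

VARIANTS = ("topological", "modified_topological")
PLACEMENTS = ("centered", "leading", "trailing")


@dataclass(frozen=True)
class EntropyProfile:
    """Per-base matrix of windowed entropy values, one row per k."""

    sequence_id: str
    window: int
    k_values: tuple[int, ...]
    matrix: np.ndarray  # K×L, float, NaN = missing
    variant: str = "modified_topological"
    filter_rule: str = FILTER_EXPECTED_COUNT

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.k_values), self.matrix.shape[1]):
            raise ValueError("profile matrix must have one row per k value")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class SVDResult:
    """Thin SVD factors with a fixed sign convention.

    Each left-singular vector is flipped so its entry sum is non-negative
    (ties broken by making its first nonzero entry positive), with the
    matching right vector flipped alongside, so the factorization is
    deterministic.
    """

    left_vectors: np.ndarray      # K×m
    singular_values: np.ndarray   # m
    right_vectors_t: np.ndarray   # m×L

    def reconstruct(self, rank: int | None = None) -> np.ndarray:
        r = len(self.singular_values) if rank is None else rank
        return (
            self.left_vectors[:, :r]
            * self.singular_values[:r]
        ) @ self.right_vectors_t[:r]


@dataclass(frozen=True)
class PositionScore:
    """Per-base scalar SVD score with the provenance that produced it."""

    sequence_id: str
    scores: np.ndarray
    rank_used: int
    window: int
    k_values: tuple[int, ...]


def _encode(residues: str) -> np.ndarray:
    return np.fromiter((_BASE_CODE[c] for c in residues), dtype=np.int64, count=len(residues))


def _kmer_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of each length-k window; −1 where the window holds an N."""
    n_pos = len(base_codes) - k + 1
    codes = np.zeros(n_pos, dtype=np.int64)
    valid = np.ones(n_pos, dtype=bool)
    for j in range(k):
        b = base_codes[j : j + n_pos]
        codes = codes * 4 + np.maximum(b, 0)
        valid &= b >= 0
    codes[~valid] = -1
    return codes


def _window_values(
    codes: np.ndarray, k: int, window: int, variant: str, filter_rule: str
) -> np.ndarray:
    """Entropy value for every window start, via an incremental k-mer census.

    Sliding the window by one base retires one k-mer and admits one, so the
    census, the distinct count, and the filtered ("kept") count are all
    maintained in O(1) per step.
    """
    m = window - k + 1          # k-mer slots per window
    n_windows = len(codes) - m + 1
    filtered = variant == "modified_topological"
    # expected-count threshold: a k-mer must appear >= window/4^k times
    threshold = window / 4**k
    t_int = math.ceil(threshold)
    rel_threshold = (
        4 ** compute_n_omega(window) / window
        if filtered and filter_rule == FILTER_LITERAL_RELATIVE
        else 0.0
    )

    counts: dict[int, int] = {}
    n_valid = 0
    kept = 0  # codes with count >= t_int (expected_count rule only)

    def add(code: int) -> None:
        nonlocal n_valid, kept
        if code < 0:
            return
        c = counts.get(code, 0) + 1
        counts[code] = c
        n_valid += 1
        if c == t_int:
            kept += 1

    def remove(code: int) -> None:
        nonlocal n_valid, kept
        if code < 0:
            return
        c = counts[code]
        if c == 1:
            del counts[code]
        else:
            counts[code] = c - 1
        n_valid -= 1
        if c == t_int:
            kept -= 1

    for j in range(m):
        add(int(codes[j]))

    values = np.empty(n_windows, dtype=float)
    log4 = math.log(4.0)
    for s in range(n_windows):
        if s > 0:
            remove(int(codes[s - 1]))
            add(int(codes[s + m - 1]))
        if n_valid == 0:
            values[s] = np.nan
            continue
        if not filtered:
            p = len(counts)
        elif filter_rule == FILTER_EXPECTED_COUNT:
            p = kept
        elif filter_rule == FILTER_LITERAL_RELATIVE:
            p = sum(1 for c in counts.values() if c / n_valid >= rel_threshold)
        else:
            raise ValueError(f"unknown filter rule {filter_rule!r}")
        values[s] = math.log(max(p, 1)) / (log4 * k)
    return values


def window_entropy_profile(
    seq: NucleotideSequence,
    window: int = 100,
    k_values: tuple[int, ...] = (2, 3, 4, 5, 6),
    variant: str = "modified_topological",
    filter_rule: str = FILTER_EXPECTED_COUNT,
    placement: str = "centered",
) -> EntropyProfile:
    """Digitize ``seq`` into a K×L per-base entropy matrix.

    Row j holds, at column i, the windowed entropy at subword length
    ``k_values[j]`` of the full-size window assigned to base i (centered
    and clamped by default).  Entries are NaN where the window holds no
    valid k-mer.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown entropy variant {variant!r}; expected one of {VARIANTS}")
    if placement not in PLACEMENTS:
        raise ValueError(f"unknown window placement {placement!r}")
    L = seq.length
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    if max(k_values) >= window:
        raise ValueError(f"subword length {max(k_values)} must be < window {window}")

    base_codes = _encode(seq.residues)
    positions = np.arange(L)
    if placement == "centered":
        starts = positions - window // 2
    elif placement == "leading":
        starts = positions
    else:
        starts = positions - window + 1
    starts = np.clip(starts, 0, L - window)

    matrix = np.empty((len(k_values), L), dtype=float)
    for row, k in enumerate(k_values):
        per_window = _window_values(
            _kmer_codes(base_codes, k), k, window, variant, filter_rule
        )
        matrix[row] = per_window[starts]
    return EntropyProfile(seq.identifier, window, tuple(k_values), matrix, variant, filter_rule)


def impute_missing(profile: EntropyProfile) -> EntropyProfile:
    """Fill NaN entries with the nearest finite entry in the same row.

    Equidistant neighbors resolve leftward.  A row with no finite entry is
    an error.
    """
    matrix = profile.matrix.copy()
    for row in matrix:
        missing = np.flatnonzero(np.isnan(row))
        if len(missing) == 0:
            continue
        finite = np.flatnonzero(~np.isnan(row))
        if len(finite) == 0:
            raise ValueError("cannot impute: a profile row has no finite entry")
        right = np.searchsorted(finite, missing)
        left = np.clip(right - 1, 0, len(finite) - 1)
        right = np.clip(right, 0, len(finite) - 1)
        dist_left = np.abs(missing - finite[left])
        dist_right = np.abs(finite[right] - missing)
        pick = np.where(dist_left <= dist_right, finite[left], finite[right])
        row[missing] = row[pick]
    return replace(profile, matrix=matrix)


def svd_decompose(matrix: np.ndarray) -> SVDResult:
    """Thin SVD with a deterministic sign convention.

    Raises on non-finite input — missing profile entries must be imputed
    first.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite entries; impute before SVD")
    u, s, vt = np.linalg.svd(matrix, full_matrices=False)
    for j in range(u.shape[1]):
        col_sum = u[:, j].sum()
        if col_sum < 0:
            flip = True
        elif col_sum > 0:
            flip = False
        else:
            nz = np.flatnonzero(u[:, j])
            flip = len(nz) > 0 and u[nz[0], j] < 0
        if flip:
            u[:, j] = -u[:, j]
            vt[j] = -vt[j]
    return SVDResult(u, s, vt)


def svd_position_score(profile: EntropyProfile, rank: int = 1) -> PositionScore:
    """Per-base score: column mean of the rank-``rank`` reconstruction."""
    K = profile.matrix.shape[0]
    if not 1 <= rank <= K:
        raise ValueError(f"rank {rank} outside [1, {K}]")
    if np.isnan(profile.matrix).any():
        profile = impute_missing(profile)
    svd = svd_decompose(profile.matrix)
    scores = svd.reconstruct(rank).mean(axis=0)
    return PositionScore(
        profile.sequence_id, scores, rank, profile.window, profile.k_values
    )
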