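"""Windowed entropy profiles and SVD position scores."""

import numpy as np
import pytest

import topentropy as tp
from conftest import naive_window_entropy


def _random_matrix(rng, k, p):
    return rng.random((k, p))


class TestWindowProfile:
    def test_homopolymer_profile_is_zero(self):
        seq = tp.homopolymer(200)
        prof = tp.window_entropy_profile(seq, 100, (2, 3, 4))
        assert prof.matrix.shape == (3, 200)
        assert np.all(prof.matrix == 0.0)

    def test_shape_one_row_per_k_one_column_per_base(self):
        seq = tp.random_sequence(300, seed=3)
        prof = tp.window_entropy_profile(seq)
        assert prof.matrix.shape == (5, 300)
        assert prof.k_values == (2, 3, 4, 5, 6)

    @pytest.mark.parametrize("variant", ["topological", "modified_topological"])
    def test_centered_column_matches_window_recompute(self, variant):
        """Column 150 must equal the entropy of bases [100, 200) per k."""
        seq = tp.random_sequence(300, seed=11)
        k_values = (2, 3, 4, 5, 6)
        prof = tp.window_entropy_profile(seq, 100, k_values, variant)
        window = seq.residues[100:200]
        filtered = variant == "modified_topological"
        for row, k in enumerate(k_values):
            expected = naive_window_entropy(window, k, filtered)
            assert prof.matrix[row, 150] == pytest.approx(expected, abs=1e-12)

    def test_edge_columns_use_clamped_full_windows(self):
        seq = tp.random_sequence(250, seed=5)
        prof = tp.window_entropy_profile(seq, 100, (3,), "topological")
        first = naive_window_entropy(seq.residues[:100], 3, False)
        last = naive_window_entropy(seq.residues[150:], 3, False)
        assert prof.matrix[0, 0] == pytest.approx(first)
        assert prof.matrix[0, 10] == pytest.approx(first)   # still clamped at 0
        assert prof.matrix[0, 249] == pytest.approx(last)

    def test_random_interior_columns_match_recompute(self, rng):
        seq = tp.random_sequence(400, seed=21)
        prof = tp.window_entropy_profile(seq, 100, (2, 4), "modified_topological")
        for i in rng.integers(50, 350, size=10):
            window = seq.residues[i - 50 : i + 50]
            assert prof.matrix[0, i] == pytest.approx(
                naive_window_entropy(window, 2, True), abs=1e-12
            )
            assert prof.matrix[1, i] == pytest.approx(
                naive_window_entropy(window, 4, True), abs=1e-12
            )

    def test_entries_bounded(self):
        seq = tp.random_sequence(500, seed=9)
        prof = tp.window_entropy_profile(seq)
        finite = prof.matrix[np.isfinite(prof.matrix)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_all_n_window_is_missing(self):
        seq = tp.NucleotideSequence("s", "N" * 150 + tp.random_sequence(150, seed=2).residues)
        prof = tp.window_entropy_profile(seq, 100, (3,), "topological")
        assert np.isnan(prof.matrix[0, 0])
        assert np.isfinite(prof.matrix[0, 299])

    def test_window_and_k_validation(self):
        seq = tp.random_sequence(50, seed=1)
        with pytest.raises(ValueError, match="window"):
            tp.window_entropy_profile(seq, 100)
        with pytest.raises(ValueError, match="subword length"):
            tp.window_entropy_profile(seq, 10, (12,))


class TestImputation:
    def _profile(self, row):
        return tp.EntropyProfile("s", 10, (2,), np.array([row], dtype=float))

    def test_identity_without_missing(self):
        prof = self._profile([0.1, 0.2, 0.3])
        out = tp.impute_missing(prof)
        np.testing.assert_array_equal(out.matrix, prof.matrix)

    def test_tie_takes_left_neighbor(self):
        out = tp.impute_missing(self._profile([0.1, np.nan, 0.3]))
        assert out.matrix[0, 1] == 0.1

    def test_run_splits_by_nearest_neighbor(self, rng):
        row = np.full(30, np.nan)
        finite_at = sorted(rng.choice(30, size=5, replace=False))
        for i in finite_at:
            row[i] = float(i)
        out = tp.impute_missing(self._profile(list(row)))
        for j in range(30):
            # brute-force nearest finite index, leftward ties
            best = min(finite_at, key=lambda i: (abs(i - j), i))
            assert out.matrix[0, j] == float(best)

    def test_fully_missing_row_errors(self):
        with pytest.raises(ValueError, match="no finite entry"):
            tp.impute_missing(self._profile([np.nan, np.nan]))


class TestSVD:
    def test_rank1_matrix_has_one_singular_value(self, rng):
        a = np.outer(rng.random(4) + 0.1, rng.random(7) + 0.1)
        svd = tp.svd_decompose(a)
        assert svd.singular_values[0] > 0
        np.testing.assert_allclose(svd.singular_values[1:], 0, atol=1e-10)
        np.testing.assert_allclose(svd.reconstruct(1), a, atol=1e-10)

    def test_reconstruction_identity(self, rng):
        for _ in range(20):
            a = _random_matrix(rng, 5, 40)
            svd = tp.svd_decompose(a)
            err = np.linalg.norm(svd.reconstruct() - a) / np.linalg.norm(a)
            assert err <= 1e-8

    def test_singular_values_match_eigenvalue_oracle(self, rng):
        """sigma_i^2 equals the eigenvalues of A A^T from an eigensolver."""
        a = _random_matrix(rng, 3, 4)
        svd = tp.svd_decompose(a)
        eigvals = np.sort(np.linalg.eigvalsh(a @ a.T))[::-1]
        np.testing.assert_allclose(svd.singular_values**2, eigvals, atol=1e-10)

    def test_orthonormal_factors_and_order(self, rng):
        a = _random_matrix(rng, 5, 30)
        svd = tp.svd_decompose(a)
        np.testing.assert_allclose(
            svd.left_vectors.T @ svd.left_vectors, np.eye(5), atol=1e-8
        )
        np.testing.assert_allclose(
            svd.right_vectors_t @ svd.right_vectors_t.T, np.eye(5), atol=1e-8
        )
        assert np.all(np.diff(svd.singular_values) <= 1e-12)
        assert np.all(svd.singular_values >= 0)

    def test_sign_convention_column_sums_non_negative(self, rng):
        for _ in range(10):
            svd = tp.svd_decompose(_random_matrix(rng, 4, 9) - 0.5)
            sums = svd.left_vectors.sum(axis=0)
            nz = np.abs(sums) > 1e-12
            assert np.all(sums[nz] >= 0)

    def test_eckart_young_residual_identity(self, rng):
        """Frobenius error of the rank-r truncation is sqrt(sum of trailing
        sigma^2), on 100 seeded matrices."""
        for _ in range(100):
            k, p = int(rng.integers(2, 7)), int(rng.integers(5, 30))
            a = _random_matrix(rng, k, p) - rng.random()
            svd = tp.svd_decompose(a)
            for r in range(1, min(k, p) + 1):
                err = np.linalg.norm(a - svd.reconstruct(r))
                expected = np.sqrt(np.sum(svd.singular_values[r:] ** 2))
                assert err == pytest.approx(expected, abs=1e-8)

    def test_non_finite_entries_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            tp.svd_decompose(np.array([[1.0, np.nan]]))


class TestPositionScore:
    def _profile_from_matrix(self, m):
        return tp.EntropyProfile("s", 10, tuple(range(2, 2 + m.shape[0])), m)

    def test_constant_profile_gives_constant_score(self):
        m = np.full((4, 25), 0.37)
        score = tp.svd_position_score(self._profile_from_matrix(m), rank=1)
        np.testing.assert_allclose(score.scores, 0.37, atol=1e-10)

    def test_full_rank_score_is_column_mean(self, rng):
        m = _random_matrix(rng, 5, 40)
        score = tp.svd_position_score(self._profile_from_matrix(m), rank=5)
        np.testing.assert_allclose(score.scores, m.mean(axis=0), atol=1e-10)

    def test_rank1_score_matches_power_iteration_oracle(self, rng):
        """Rank-1 reconstruction vs an independent power-iteration on A A^T."""
        a = _random_matrix(rng, 5, 500)
        score = tp.svd_position_score(self._profile_from_matrix(a), rank=1)
        u = np.ones(5)
        for _ in range(500):
            u = a @ (a.T @ u)
            u /= np.linalg.norm(u)
        if u.sum() < 0:
            u = -u
        rank1 = np.outer(u, u @ a)
        np.testing.assert_allclose(score.scores, rank1.mean(axis=0), atol=1e-6)

    def test_score_is_deterministic(self):
        seq = tp.random_sequence(300, seed=13)
        prof = tp.window_entropy_profile(seq)
        s1 = tp.svd_position_score(prof).scores
        s2 = tp.svd_position_score(tp.window_entropy_profile(seq)).scores
        np.testing.assert_array_equal(s1, s2)

    def test_rank_out_of_range(self):
        prof = self._profile_from_matrix(np.ones((3, 5)))
        with pytest.raises(ValueError, match="rank"):
            tp.svd_position_score(prof, rank=4)

    def test_repeat_segments_score_below_background(self):
        """Low-complexity segments must pull the score down (20 seeds)."""
        wins = 0
        for seed in range(20):
            seq, truth = tp.build_benchmark(tp.aj_benchmark_spec(seed=seed))
            score = tp.svd_position_score(tp.window_entropy_profile(seq))
            region = tp.GenomicInterval(seq.identifier, 0, seq.length, "other")
            mask = truth.label_mask("exon", seq.identifier, region)
            wins += score.scores[mask].mean() < score.scores[~mask].mean()
        assert wins >= 19
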