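import numpy as np
import pytest

from epitrace.smoothing import (
    SimilarityMatrix,
    build_similarity,
    diffusion_smooth,
    nnls_solve,
    rank_normalize,
    select_variable_peaks,
)

from conftest import make_matrix


def projected_gradient_nnls(A, b, tol=1e-10, max_iter=200_000):
    """Independent NNLS oracle: projected gradient descent on ||Ax-b||^2."""
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    L = np.linalg.norm(A, 2) ** 2
    step = 1.0 / L
    x = np.zeros(A.shape[1])
    AtA = A.T @ A
    Atb = A.T @ b
    for _ in range(max_iter):
        grad = AtA @ x - Atb
        x_new = np.maximum(x - step * grad, 0.0)
        if np.max(np.abs(x_new - x)) < tol:
            return x_new
        x = x_new
    return x


class TestSelectVariablePeaks:
    def test_five_percent_of_100_is_5(self, rng):
        X = rng.integers(0, 5, size=(100, 10))
        assert len(select_variable_peaks(make_matrix(X))) == 5

    def test_constant_peak_never_beats_variable_peak(self):
        X = np.zeros((2, 4))
        X[0, :] = 3.0            # constant -> zero variance
        X[1, :] = [0, 6, 0, 6]   # positive variance
        sel = select_variable_peaks(make_matrix(X), fraction=0.5)
        assert sel.tolist() == [1]

    def test_matches_full_sort_oracle(self, rng):
        X = rng.integers(0, 8, size=(40, 12)).astype(float)
        m = make_matrix(X)
        sel = select_variable_peaks(m, fraction=0.25)
        mean = X.mean(axis=1)
        var = X.var(axis=1)
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1), 0.0)
        # stable sort = index tie-break
        order = np.argsort(-disp, kind="stable")[:10]
        assert sorted(sel.tolist()) == sorted(order.tolist())

    def test_tie_break_prefers_lower_index(self):
        X = np.tile([0.0, 4.0], (6, 1))  # all peaks identical dispersion
        sel = select_variable_peaks(make_matrix(X), fraction=0.5)
        assert sel.tolist() == [0, 1, 2]

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_invalid_fraction_rejected(self, small_matrix, fraction):
        with pytest.raises(ValueError, match="fraction"):
            select_variable_peaks(small_matrix, fraction=fraction)


class TestBuildSimilarity:
    def test_identical_cells_rows_sum_to_one(self):
        X = np.tile([[1.0], [0.0], [3.0], [2.0]], (1, 2))
        S = build_similarity(make_matrix(X), np.arange(4))
        np.testing.assert_allclose(S.weights.sum(axis=1), 1.0, atol=1e-9)
        assert S.weights[0, 1] > 0

    def test_hand_computed_three_cell_case(self):
        # cells 1,2 identical; cell 3 reversed: corr(1,2)=1, corr(.,3)=-1
        v = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.stack([v, v, v[::-1]], axis=1)
        S = build_similarity(make_matrix(X), np.arange(4))
        W = S.weights
        # negative correlations fell below the mean and were zeroed
        assert W[0, 2] == 0 and W[1, 2] == 0
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-9)
        assert W[0, 1] == pytest.approx(0.5)  # diag 1 and corr 1 share the row

    def test_row_sums_on_random_cells(self, rng):
        X = rng.poisson(2.0, size=(30, 50)).astype(float)
        S = build_similarity(make_matrix(X), np.arange(30))
        np.testing.assert_allclose(S.weights.sum(axis=1), 1.0, atol=1e-9)
        assert (S.weights >= 0).all()

    def test_single_cell_rejected(self):
        X = np.ones((4, 1))
        with pytest.raises(ValueError, match="single cell"):
            build_similarity(make_matrix(X), np.arange(4))

    def test_constant_cell_becomes_identity_row(self):
        X = np.array(
            [[1.0, 5.0, 2.0], [2.0, 5.0, 4.0], [3.0, 5.0, 1.0], [4.0, 5.0, 3.0]]
        )  # cell 1 constant -> correlation 0 with everyone
        S = build_similarity(make_matrix(X), np.arange(4))
        row = S.weights[1]
        assert row[1] == 1.0 and row.sum() == 1.0


class TestNnlsSolve:
    def test_identity_system(self):
        x, res = nnls_solve(np.eye(3), np.array([3.0, 1.0, 2.0]))
        np.testing.assert_allclose(x, [3, 1, 2], atol=1e-12)
        assert res == pytest.approx(0.0, abs=1e-12)

    def test_negative_component_clamped(self):
        x, res = nnls_solve(np.eye(2), np.array([-1.0, 2.0]))
        np.testing.assert_allclose(x, [0.0, 2.0], atol=1e-12)
        assert res == pytest.approx(1.0, abs=1e-10)

    def test_matches_projected_gradient_oracle(self, rng):
        for _ in range(20):
            A = rng.normal(size=(15, 15)) + 4 * np.eye(15)  # well conditioned
            b = rng.normal(size=15) * 3
            x, _ = nnls_solve(A, b)
            x_or = projected_gradient_nnls(A, b)
            assert (x >= 0).all()
            np.testing.assert_allclose(x, x_or, atol=1e-6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            nnls_solve(np.array([[np.nan, 0], [0, 1.0]]), np.array([1.0, 1.0]))


class TestDiffusionSmooth:
    @pytest.mark.parametrize("mode", ["reaction", "pure"])
    def test_identity_similarity_is_fixed_point(self, mode):
        x0 = np.array([5.0, 1.0, 3.0])
        x, sm, n, conv = diffusion_smooth(np.eye(3), x0, mode=mode)
        np.testing.assert_allclose(sm, x0, atol=1e-12)
        assert conv

    @pytest.mark.parametrize("mode", ["reaction", "pure"])
    def test_two_by_two_averaging_converges_to_mean(self, mode):
        S = np.full((2, 2), 0.5)
        x0 = np.array([0.0, 1.0])
        _, sm, _, conv = diffusion_smooth(S, x0, tol=1e-12, max_iter=2000, mode=mode)
        np.testing.assert_allclose(sm, [0.5, 0.5], atol=1e-9)
        assert conv

    @pytest.mark.parametrize("mode", ["reaction", "pure"])
    def test_output_within_input_bounds_for_row_stochastic(self, rng, mode):
        for _ in range(50):
            n = int(rng.integers(2, 10))
            W = rng.uniform(size=(n, n))
            W = W / W.sum(axis=1, keepdims=True)
            x0 = rng.normal(size=n) * 10
            _, sm, _, _ = diffusion_smooth(W, x0, mode=mode)
            assert sm.min() >= x0.min() - 1e-9
            assert sm.max() <= x0.max() + 1e-9

    def test_pure_mode_contracts_toward_mean_for_doubly_stochastic(self, rng):
        n = 8
        M = rng.uniform(size=(n, n))
        M = (M + M.T) / 2
        # Sinkhorn to doubly stochastic
        for _ in range(500):
            M /= M.sum(axis=1, keepdims=True)
            M = (M + M.T) / 2
        x = rng.normal(size=n)
        xbar = x.mean()
        for _ in range(20):
            x_new = 0.5 * x + 0.5 * (M @ x)
            assert np.max(np.abs(x_new - xbar)) <= np.max(np.abs(x - xbar)) + 1e-12
            x = x_new

    def test_reaction_mode_fixed_point_matches_closed_form(self, rng):
        n = 6
        W = rng.uniform(size=(n, n))
        W = W / W.sum(axis=1, keepdims=True)
        x0 = rng.normal(size=n)
        w = 0.5
        x, sm, _, conv = diffusion_smooth(W, x0, w=w, tol=1e-12, max_iter=5000)
        expected = w * np.linalg.solve(np.eye(n) - (1 - w) * W, x0)
        np.testing.assert_allclose(x, expected, atol=1e-9)
        np.testing.assert_allclose(sm, W @ expected, atol=1e-9)
        assert conv

    def test_divergence_guard_on_malformed_matrix(self):
        bad = np.full((2, 2), 50.0)  # not row-stochastic
        with pytest.raises(FloatingPointError):
            diffusion_smooth(bad, np.array([1.0, 2.0]), mode="pure", max_iter=100)

    def test_invalid_weight_rejected(self):
        with pytest.raises(ValueError, match="weight"):
            diffusion_smooth(np.eye(2), np.array([1.0, 2.0]), w=1.0)


class TestRankNormalize:
    def test_single_cell_example(self):
        np.testing.assert_allclose(
            rank_normalize(np.array([5.0, 1.0, 3.0])), [1.0, 0.0, 0.5]
        )

    def test_bulk_mode_reverses(self):
        np.testing.assert_allclose(
            rank_normalize(np.array([5.0, 1.0, 3.0]), mode="bulk"), [0.0, 1.0, 0.5]
        )

    def test_constant_vector_gets_half(self):
        np.testing.assert_allclose(
            rank_normalize(np.full(4, 2.0)), [0.5, 0.5, 0.5, 0.5]
        )

    def test_singleton_returns_half(self):
        assert rank_normalize(np.array([42.0])).tolist() == [0.5]

    def test_extremes_hit_zero_and_one(self, rng):
        v = rng.normal(size=25)
        r = rank_normalize(v)
        assert r.min() == 0.0 and r.max() == 1.0
        # order preserved
        assert np.array_equal(np.argsort(r), np.argsort(v))

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            rank_normalize(np.array([1.0, np.nan]))


class TestSimilarityMatrixInvariants:
    def test_rejects_non_stochastic_rows(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimilarityMatrix(np.array([[0.5, 0.2], [0.5, 0.5]]), 0.0)

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError, match="non-negative"):
            SimilarityMatrix(np.array([[1.5, -0.5], [0.5, 0.5]]), 0.0)
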