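import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlgrlmf import (
    HyperParams,
    LatentFactors,
    build_laplacian,
    build_laplacian_pair,
    fit,
    generate,
    gradients,
    infer_new_latent,
    load_model,
    logistic_prob,
    neighbor_sparsify,
    objective_value,
    predict_scores,
    save_model,
    second_order_affinity,
    SyntheticConfig,
)


def random_problem(rng, d, t, k, alpha=0.1, beta=0.1, n=5.0):
    A = (rng.random((d, t)) < 0.3).astype(float)
    DS = rng.random((d, d))
    DS = (DS + DS.T) / 2
    np.fill_diagonal(DS, 1.0)
    TS = rng.random((t, t))
    TS = (TS + TS.T) / 2
    np.fill_diagonal(TS, 1.0)
    K = min(3, d - 1, t - 1)
    lap = build_laplacian_pair(DS, TS, K)
    factors = LatentFactors(U=rng.normal(size=(d, k)), V=rng.normal(size=(t, k)))
    hp = HyperParams(k=k, n_weight=n, K=K, alpha=alpha, beta=beta, seed=0)
    return A, DS, TS, lap, factors, hp


def objective_bruteforce(A, factors, lap, hp, mask=None):
    """Literal cell-by-cell re-implementation of the objective."""
    U, V = factors.U, factors.V
    n = hp.n_weight
    total = 0.0
    d, t = A.shape
    for i in range(d):
        for j in range(t):
            s = float(U[i] @ V[j])
            w = 1.0 if mask is None else mask[i, j]
            total += w * ((1 + n * A[i, j] - A[i, j]) * math.log1p(math.exp(s)) - n * A[i, j] * s)
    I_d, I_t = np.eye(d), np.eye(t)
    total += hp.alpha * np.trace(U.T @ (lap.L_D + I_d) @ U)
    total += hp.beta * np.trace(V.T @ (lap.L_T + I_t) @ V)
    return total


class TestLogisticProb:
    def test_closed_form_values(self):
        assert logistic_prob(np.array([0.0]))[0] == 0.5
        e = math.exp(1.0)
        assert logistic_prob(np.array([1.0]))[0] == pytest.approx(e / (1 + e), abs=1e-13)

    def test_saturation_stays_inside_unit_interval(self):
        out = logistic_prob(np.array([40.0, 1e3, -1e3]))
        assert abs(1.0 - out[0]) < 1e-12
        assert np.all(out > 0) and np.all(out < 1)
        assert np.isfinite(out).all()

    def test_rejects_nonfinite_scores(self):
        with pytest.raises(ValueError, match="index"):
            logistic_prob(np.array([[0.0, np.nan], [1.0, 2.0]]))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-1e3, max_value=1e3, allow_nan=False))
    def test_bounds_property(self, x):
        p = logistic_prob(np.array([x]))[0]
        assert 0.0 < p < 1.0


class TestNeighborSparsify:
    def test_hand_example_k1(self):
        sim = np.array([[1, 0.9, 0.1], [0.9, 1, 0.2], [0.1, 0.2, 1]])
        out = neighbor_sparsify(sim, K=1)
        expected = np.zeros((3, 3))
        expected[1, 0] = 0.9  # column 0 keeps its nearest non-self neighbor, row 1
        expected[0, 1] = 0.9
        expected[1, 2] = 0.2
        np.testing.assert_array_equal(out, expected)

    def test_full_neighborhood_zeroes_only_diagonal(self):
        rng = np.random.default_rng(3)
        S = rng.random((5, 5))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        out = neighbor_sparsify(S, K=4)
        expected = S.copy()
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_array_equal(out, expected)

    def test_identity_similarity_gives_zero_graph(self):
        assert neighbor_sparsify(np.eye(4), K=2).sum() == 0.0

    @pytest.mark.parametrize("K", [0, 5])
    def test_out_of_range_neighbor_count(self, K):
        with pytest.raises(ValueError, match="out of range"):
            neighbor_sparsify(np.eye(5), K)

    @pytest.mark.parametrize("seed", range(5))
    def test_column_support_invariants(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.random((8, 8))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        K = int(rng.integers(1, 7))
        out = neighbor_sparsify(S, K)
        assert np.all(np.diag(out) == 0)
        for j in range(8):
            nz = np.nonzero(out[:, j])[0]
            assert len(nz) <= K
            np.testing.assert_array_equal(out[nz, j], S[nz, j])


class TestSecondOrderAffinity:
    def test_small_cases(self):
        np.testing.assert_array_equal(second_order_affinity(np.eye(3)), np.eye(3))
        np.testing.assert_array_equal(second_order_affinity(np.zeros((3, 3))), np.zeros((3, 3)))
        out = second_order_affinity(np.array([[0.0, 0.9], [0.9, 0.0]]))
        np.testing.assert_allclose(out, [[0.81, 0.0], [0.0, 0.81]], atol=1e-15)

    @pytest.mark.parametrize("seed", range(5))
    def test_symmetric_psd_despite_asymmetric_input(self, seed):
        rng = np.random.default_rng(seed)
        S = rng.random((7, 7))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        M = neighbor_sparsify(S, 2)
        assert not np.allclose(M, M.T)  # K-NN sparsification is asymmetric
        W = second_order_affinity(M)
        np.testing.assert_allclose(W, W.T, atol=1e-10)
        assert np.linalg.eigvalsh(W).min() >= -1e-8


class TestLaplacian:
    def test_two_node_graph(self):
        L, D = build_laplacian(np.array([[0.0, 0.7], [0.7, 0.0]]))
        np.testing.assert_allclose(L, [[0.7, -0.7], [-0.7, 0.7]])
        np.testing.assert_allclose(D, np.diag([0.7, 0.7]))

    def test_rejects_asymmetric_affinity(self):
        with pytest.raises(ValueError, match="asymmetric"):
            build_laplacian(np.array([[0.0, 1.0], [0.5, 0.0]]))

    @pytest.mark.parametrize("seed", range(4))
    def test_row_sums_psd_and_quadratic_form(self, seed):
        rng = np.random.default_rng(seed)
        W = rng.random((6, 6))
        W = (W + W.T) / 2
        L, _D = build_laplacian(W)
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-8)
        assert np.linalg.eigvalsh(L).min() >= -1e-8
        # Tr(U^T L U) = 1/2 sum_ij W_ij ||u_i - u_j||^2
        U = rng.normal(size=(6, 3))
        quad = sum(
            0.5 * W[i, j] * np.sum((U[i] - U[j]) ** 2) for i in range(6) for j in range(6)
        )
        np.testing.assert_allclose(np.trace(U.T @ L @ U), quad, rtol=1e-10)


class TestObjective:
    def test_closed_form_at_zero_factors(self):
        rng = np.random.default_rng(0)
        A = (rng.random((6, 5)) < 0.4).astype(float)
        m = A.sum()
        z = A.size - m
        lap = build_laplacian_pair(np.eye(6), np.eye(5), 2)
        hp = HyperParams(k=3, n_weight=5, K=2, alpha=0.3, beta=0.7)
        zero = LatentFactors(U=np.zeros((6, 3)), V=np.zeros((5, 3)))
        assert objective_value(A, zero, lap, hp) == pytest.approx((z + 5 * m) * math.log(2), abs=1e-10)
        assert objective_value(np.zeros((6, 5)), zero, lap, hp) == pytest.approx(30 * math.log(2), abs=1e-10)

    @pytest.mark.parametrize("use_mask", [False, True])
    def test_matches_bruteforce_summation(self, use_mask):
        rng = np.random.default_rng(42)
        A, DS, TS, lap, factors, hp = random_problem(rng, d=4, t=3, k=2)
        mask = (rng.random((4, 3)) < 0.7).astype(float) if use_mask else None
        got = objective_value(A, factors, lap, hp, weight_mask=mask)
        want = objective_bruteforce(A, factors, lap, hp, mask=mask)
        assert got == pytest.approx(want, abs=1e-10)

    def test_shape_mismatch(self):
        lap = build_laplacian_pair(np.eye(4), np.eye(3), 2)
        hp = HyperParams(k=2)
        bad = LatentFactors(U=np.zeros((5, 2)), V=np.zeros((3, 2)))
        with pytest.raises(ValueError, match="rows"):
            objective_value(np.zeros((4, 3)), bad, lap, hp)


def finite_difference_gradients(A, factors, lap, hp, mask=None, h=1e-6):
    gU = np.zeros_like(factors.U)
    gV = np.zeros_like(factors.V)
    for M, G in ((factors.U, gU), (factors.V, gV)):
        it = np.nditer(M, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = M[idx]
            M[idx] = orig + h
            f_plus = objective_value(A, factors, lap, hp, mask)
            M[idx] = orig - h
            f_minus = objective_value(A, factors, lap, hp, mask)
            M[idx] = orig
            G[idx] = (f_plus - f_minus) / (2 * h)
    return gU, gV


class TestGradients:
    def test_origin_is_stationary(self):
        lap = build_laplacian_pair(np.eye(5), np.eye(4), 2)
        hp = HyperParams(k=2, alpha=0.1, beta=0.1)
        zero = LatentFactors(U=np.zeros((5, 2)), V=np.zeros((4, 2)))
        A = np.zeros((5, 4))
        A[0, 0] = 1
        gU, gV = gradients(A, zero, lap, hp)
        np.testing.assert_array_equal(gU, 0.0)
        np.testing.assert_array_equal(gV, 0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_central_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        d, t, k = rng.integers(3, 9), rng.integers(3, 9), rng.integers(1, 5)
        A, DS, TS, lap, factors, hp = random_problem(rng, int(d), int(t), int(k))
        gU, gV = gradients(A, factors, lap, hp)
        fU, fV = finite_difference_gradients(A, factors, lap, hp)
        for got, want in ((gU, fU), (gV, fV)):
            rel = np.linalg.norm(got - want) / np.linalg.norm(want)
            assert rel < 1e-5

    def test_masked_gradient_matches_masked_finite_differences(self):
        rng = np.random.default_rng(11)
        A, DS, TS, lap, factors, hp = random_problem(rng, 5, 4, 2)
        mask = np.ones((5, 4))
        mask[1, 2] = mask[3, 0] = 0.0
        gU, gV = gradients(A, factors, lap, hp, weight_mask=mask)
        fU, fV = finite_difference_gradients(A, factors, lap, hp, mask=mask)
        np.testing.assert_allclose(gU, fU, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(gV, fV, rtol=1e-5, atol=1e-8)

    def test_all_ones_simplification_without_graphs(self):
        # With alpha = beta = 0 and A all ones the U-gradient collapses to n (P - A) V.
        rng = np.random.default_rng(5)
        d, t, k, n = 5, 4, 3, 5.0
        A = np.ones((d, t))
        lap = build_laplacian_pair(np.eye(d), np.eye(t), 2)
        hp = HyperParams(k=k, n_weight=n, alpha=0.0, beta=0.0)
        factors = LatentFactors(U=rng.normal(size=(d, k)), V=rng.normal(size=(t, k)))
        P = logistic_prob(factors.U @ factors.V.T)
        gU, _ = gradients(A, factors, lap, hp)
        np.testing.assert_allclose(gU, n * (P - A) @ factors.V, rtol=1e-12)


class TestFit:
    def test_objective_decreases_and_trace_monotone_under_plain_gd(self):
        b = generate(SyntheticConfig(seed=0)).bundle
        hp = HyperParams(k=5, optimizer="plain_gd", learning_rate=1e-4, max_iter=60, tol=1e-15, seed=0)
        res = fit(b.interactions, b.drug_sim, b.target_sim, hp)
        trace = np.array(res.objective_trace)
        assert trace[-1] < trace[0]
        assert np.all(np.diff(trace[:51]) <= 0)

    def test_deterministic_under_fixed_seed(self, small_bundle):
        hp = HyperParams(k=3, max_iter=40, seed=123)
        r1 = fit(small_bundle.interactions, small_bundle.drug_sim, small_bundle.target_sim, hp)
        r2 = fit(small_bundle.interactions, small_bundle.drug_sim, small_bundle.target_sim, hp)
        np.testing.assert_array_equal(r1.factors.U, r2.factors.U)
        np.testing.assert_array_equal(r1.factors.V, r2.factors.V)
        assert r1.objective_trace == r2.objective_trace

    def test_dimension_mismatch_names_axis(self, small_bundle):
        hp = HyperParams(k=3)
        with pytest.raises(ValueError, match="drugs"):
            fit(small_bundle.interactions, np.eye(5), small_bundle.target_sim, hp)
        with pytest.raises(ValueError, match="targets"):
            fit(small_bundle.interactions, small_bundle.drug_sim, np.eye(5), hp)

    def test_divergence_raises_with_advice(self, small_bundle):
        hp = HyperParams(k=3, optimizer="plain_gd", learning_rate=1e120, max_iter=5, seed=0)
        with pytest.raises(FloatingPointError, match="learning rate"):
            fit(small_bundle.interactions, small_bundle.drug_sim, small_bundle.target_sim, hp)


class TestPredict:
    def test_zero_factors_give_half(self):
        preds = predict_scores(LatentFactors(U=np.zeros((3, 2)), V=np.zeros((4, 2))))
        np.testing.assert_array_equal(preds.probs, 0.5)

    def test_unit_inner_product(self):
        preds = predict_scores(LatentFactors(U=np.array([[1.0]]), V=np.array([[1.0]])))
        e = math.exp(1.0)
        assert preds.probs[0, 0] == pytest.approx(e / (1 + e), abs=1e-13)

    def test_scaling_sharpens_probabilities(self):
        rng = np.random.default_rng(2)
        U, V = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        p1 = predict_scores(LatentFactors(U=U, V=V)).probs
        p2 = predict_scores(LatentFactors(U=3 * U, V=V)).probs
        scores = U @ V.T
        assert np.all(p2[scores > 0] > p1[scores > 0])
        assert np.all(p2[scores < 0] < p1[scores < 0])


class TestInferNewLatent:
    def test_single_perfect_neighbor(self):
        U = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_array_equal(infer_new_latent(np.array([1.0, 0.0]), U, K=1), U[0])

    def test_equal_weights_average(self):
        U = np.array([[1.0, 2.0], [3.0, 4.0]])
        np.testing.assert_allclose(infer_new_latent(np.array([0.5, 0.5]), U, K=2), [2.0, 3.0])

    def test_weighted_mean(self):
        U = np.array([[1.0, 0.0], [0.0, 1.0]])
        got = infer_new_latent(np.array([0.6, 0.3]), U, K=2)
        np.testing.assert_allclose(got, np.array([0.6, 0.3]) / 0.9)

    def test_zero_similarity_falls_back_to_origin(self):
        got = infer_new_latent(np.zeros(3), np.ones((3, 2)), K=2)
        np.testing.assert_array_equal(got, 0.0)

    def test_empty_training_set(self):
        with pytest.raises(ValueError, match="empty"):
            infer_new_latent(np.zeros(0), np.zeros((0, 2)), K=1)


def test_model_serialization_roundtrips_bitwise(tmp_path, small_bundle):
    hp = HyperParams(k=3, max_iter=20, seed=9)
    res = fit(small_bundle.interactions, small_bundle.drug_sim, small_bundle.target_sim, hp)
    path = tmp_path / "model.json"
    save_model(path, res.factors, small_bundle.interactions.drug_ids, small_bundle.interactions.target_ids, hp)
    factors, drug_ids, target_ids, hp_back = load_model(path)
    np.testing.assert_array_equal(factors.U, res.factors.U)
    np.testing.assert_array_equal(factors.V, res.factors.V)
    assert drug_ids == small_bundle.interactions.drug_ids
    assert target_ids == small_bundle.interactions.target_ids
    assert hp_back == hp
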