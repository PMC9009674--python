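import numpy as np
import pytest

from sigselect import MutationTypeMatrix, balanced_folds, kl_divergence
from sigselect.ecm import (
    PoissonNMF,
    cm_update,
    derive_seeds,
    e_step,
    fit_ecm,
    fit_multistart,
    init_impute,
    random_init,
)

from .conftest import exact_low_rank_matrix


def masked_instance(P=12, N=10, seed=0, mean=6.0):
    g = np.random.default_rng(seed)
    V = MutationTypeMatrix(g.poisson(mean, size=(P, N)))
    mask = balanced_folds(P, N, 5)[0]
    return V, mask


class TestInitImpute:
    def test_row_median_of_training_cells(self):
        V = np.array([[2, 4, 6, 100], [1, 1, 1, 1]])
        mask = np.zeros((2, 4), dtype=bool)
        mask[0, 3] = True  # hold out the 100
        V0 = init_impute(V, mask)
        assert V0[0, 3] == 4.0  # median of {2, 4, 6}
        np.testing.assert_array_equal(V0[1], [1, 1, 1, 1])

    def test_empty_mask_is_identity(self, small_counts):
        np.testing.assert_array_equal(
            init_impute(small_counts, None), small_counts.counts
        )

    def test_held_out_values_never_read(self):
        V, mask = masked_instance(seed=3)
        corrupted = V.counts.copy()
        corrupted[mask.held_out] = 10**6
        np.testing.assert_array_equal(
            init_impute(V, mask), init_impute(corrupted, mask)
        )

    def test_fully_held_out_row_raises(self):
        mask = np.ones((2, 3), dtype=bool)
        mask[1] = False
        with pytest.raises(ValueError, match="row 0"):
            init_impute(np.ones((2, 3)), mask)


class TestRandomInit:
    def test_deterministic_per_seed(self):
        V0 = np.full((6, 4), 5.0)
        a = random_init(6, 4, 2, seed=9, V0=V0)
        b = random_init(6, 4, 2, seed=9, V0=V0)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_profile_columns_sum_to_one_and_positive(self):
        W0, H0 = random_init(8, 5, 3, seed=1, V0=np.full((8, 5), 2.0))
        np.testing.assert_allclose(W0.sum(axis=0), 1.0, rtol=1e-12)
        assert (W0 > 0).all() and (H0 > 0).all()

    def test_activity_columns_match_completed_totals(self):
        g = np.random.default_rng(4)
        V0 = g.poisson(10.0, size=(8, 5)).astype(float)
        _, H0 = random_init(8, 5, 3, seed=1, V0=V0)
        np.testing.assert_allclose(H0.sum(axis=0), V0.sum(axis=0), rtol=1e-12)


class TestEStep:
    def test_held_cell_gets_model_mean(self):
        V = np.zeros((1, 2))
        mask = np.array([[True, False]])
        W = np.array([[0.5, 0.5]])
        H = np.array([[2.0, 2.0], [2.0, 2.0]])
        Vstar = e_step(V, mask, W, H)
        assert Vstar[0, 0] == pytest.approx(2.0)
        assert Vstar[0, 1] == 0.0  # observed cell untouched

    def test_empty_mask_returns_v(self, small_counts):
        W = np.ones((12, 2))
        H = np.ones((2, 10))
        np.testing.assert_array_equal(
            e_step(small_counts, None, W, H), small_counts.counts
        )


class TestCMUpdate:
    def test_fixed_point_at_exact_factorization(self, rng):
        W = rng.uniform(0.5, 1.0, size=(6, 2))
        H = rng.uniform(0.5, 1.0, size=(2, 5))
        Vstar = W @ H
        W1, H1 = cm_update(Vstar, W, H)
        np.testing.assert_allclose(W1, W, atol=1e-12)
        np.testing.assert_allclose(H1, H, atol=1e-12)

    def test_hand_computed_two_by_two(self):
        # V* = [[4,0],[0,4]], rank 1, W = (0.5, 0.5)^T, H = (4, 4):
        # WH = [[2,2],[2,2]], R = [[2,0],[0,2]], R@H^T = (8,8)^T, rowsum H = 8
        # so W' = W; then W'^T R = (1,1), colsum W' = 1, so H' = H.
        W = np.array([[0.5], [0.5]])
        H = np.array([[4.0, 4.0]])
        W1, H1 = cm_update(np.array([[4.0, 0.0], [0.0, 4.0]]), W, H)
        np.testing.assert_allclose(W1, W, atol=1e-12)
        np.testing.assert_allclose(H1, H, atol=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_never_increases_divergence(self, seed):
        g = np.random.default_rng(seed)
        Vstar = g.poisson(5.0, size=(7, 6)).astype(float)
        W = g.uniform(0.1, 1.0, size=(7, 2))
        H = g.uniform(0.1, 5.0, size=(2, 6))
        before = kl_divergence(Vstar, W @ H)
        W1, H1 = cm_update(Vstar, W, H)
        after = kl_divergence(Vstar, W1 @ H1)
        assert after <= before + 1e-9


class TestFitECM:
    def test_noiseless_rank_one_recovery(self):
        V, _, _ = exact_low_rank_matrix(10, 8, 1, seed=5)
        fit = fit_ecm(V, None, 1, seed=0)
        rel = np.abs(fit.predicted() - V.counts) / np.maximum(V.counts, 1)
        assert rel.max() < 1e-4

    def test_engine_iteration_matches_public_ops(self):
        """One internal loop pass equals e_step followed by cm_update."""
        V, mask = masked_instance(seed=11)
        model = PoissonNMF(V, 2, mask)
        W0, H0 = random_init(*V.shape, 2, seed=5, V0=model._completed())
        W1, H1, _, _ = model._loop(W0.copy(), H0.copy(), 1e-300, 1)
        W2, H2 = cm_update(e_step(V, mask, W0, H0), W0, H0)
        np.testing.assert_allclose(W1, W2, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(H1, H2, rtol=1e-10, atol=1e-14)

    def test_loglik_path_monotone_on_masked_instances(self):
        for seed in range(10):
            V, mask = masked_instance(seed=seed)
            fit = fit_ecm(V, mask, 2, seed=seed, keep_path=True, max_iterations=200)
            deltas = np.diff(fit.loglik_path)
            assert deltas.min() >= -1e-9 * (np.abs(fit.loglik_path[:-1]).max() + 1)

    def test_mask_independence_of_observed_fit(self):
        """Corrupting held-out counts cannot change the fit."""
        V, mask = masked_instance(seed=2)
        corrupted = V.counts.copy()
        corrupted[mask.held_out] = 999
        a = fit_ecm(V, mask, 2, seed=4)
        b = fit_ecm(MutationTypeMatrix(corrupted), mask, 2, seed=4)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)

    def test_scale_consistency_on_exact_input(self):
        V, _, _ = exact_low_rank_matrix(10, 8, 1, seed=7)
        c = 3
        fit1 = fit_ecm(V, None, 1, seed=0)
        fitc = fit_ecm(MutationTypeMatrix(c * V.counts), None, 1, seed=0)
        np.testing.assert_allclose(
            fitc.predicted(), c * fit1.predicted(), rtol=1e-3
        )

    def test_nondecreasing_rank_capacity(self):
        """Final observed loglik cannot worsen with more signatures (on a
        well-determined instance with shared starting conditions)."""
        V, mask = masked_instance(P=14, N=12, seed=8, mean=20.0)
        lls = [
            fit_multistart(V, mask, r, n_starts=5, master_seed=1).observed_loglik
            for r in (1, 2, 3)
        ]
        assert lls[0] <= lls[1] + 1e-6 and lls[1] <= lls[2] + 1e-6


def lee_seung_reference(V, W, H, n_iter):
    """Independent plain KL-NMF multiplicative updates (no missing data)."""
    V = np.asarray(V, dtype=float)
    W = W.copy()
    H = H.copy()
    for _ in range(n_iter):
        WH = np.maximum(W @ H, 1e-12)
        W = W * ((V / WH) @ H.T) / np.maximum(H.sum(axis=1), 1e-12)
        W = np.maximum(W, 1e-12)
        WH = np.maximum(W @ H, 1e-12)
        H = H * (W.T @ (V / WH)) / np.maximum(W.sum(axis=0), 1e-12)[:, None]
        H = np.maximum(H, 1e-12)
    return W, H


def test_empty_mask_equals_standard_multiplicative_updates(rng):
    """With nothing held out the ECM iterates coincide with the classic
    KL-NMF multiplicative-update algorithm started from the same point."""
    V = rng.poisson(6.0, size=(10, 8))
    model = PoissonNMF(MutationTypeMatrix(V), 2, None)
    W0, H0 = random_init(10, 8, 2, seed=3, V0=model._completed())
    Wr, Hr = lee_seung_reference(V, W0, H0, 20)
    We, He, _, _ = model._loop(W0.copy(), H0.copy(), 1e-300, 20)
    np.testing.assert_allclose(We, Wr, rtol=1e-10, atol=1e-12)
    np.testing.assert_allclose(He, Hr, rtol=1e-10, atol=1e-12)


class TestMultistart:
    def test_returns_best_loglik_over_starts(self):
        V, mask = masked_instance(seed=6)
        model = PoissonNMF(V, 2, mask)
        best = model.fit_multistart(n_starts=6, master_seed=3, fold_index=1)
        singles = [
            model.fit(seed=s).observed_loglik
            for s in derive_seeds(3, 1, 2, 6)
        ]
        assert best.observed_loglik == pytest.approx(max(singles), rel=1e-12)

    def test_worker_count_does_not_change_result(self):
        V, mask = masked_instance(seed=9)
        a = fit_multistart(V, mask, 2, n_starts=6, master_seed=7, n_jobs=1)
        b = fit_multistart(V, mask, 2, n_starts=6, master_seed=7, n_jobs=2)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)
        assert a.seed == b.seed

    def test_seed_derivation_is_stable_and_bounded(self):
        seeds = derive_seeds(42, 3, 5, 10)
        assert seeds == derive_seeds(42, 3, 5, 10)
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2**31 for s in seeds)

    def test_default_start_count_matches_method(self):
        from sigselect.ecm import DEFAULT_MAX_ITERATIONS, DEFAULT_N_STARTS, DEFAULT_TOL

        assert DEFAULT_N_STARTS == 300
        assert DEFAULT_TOL == 1e-5
        assert DEFAULT_MAX_ITERATIONS == 2000
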