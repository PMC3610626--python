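"""Objectives, gradients, Procrustes projection, and optimizer contracts."""

import numpy as np
import pytest

from strflearn import learning, patches, stimgen


def fd_gradient(obj_fn, B, Z, eps=1e-5):
    g = np.zeros_like(B)
    for i in range(B.shape[0]):
        for j in range(B.shape[1]):
            Bp, Bm = B.copy(), B.copy()
            Bp[i, j] += eps
            Bm[i, j] -= eps
            g[i, j] = (obj_fn(Bp.T @ Z) - obj_fn(Bm.T @ Z)) / (2 * eps)
    return g


class TestResponses:
    def test_identity_filters(self, rng):
        Z = rng.standard_normal((5, 20))
        np.testing.assert_array_equal(learning.compute_responses(np.eye(5), Z), Z)

    def test_unit_column_self_response(self, rng):
        Z = rng.standard_normal((6, 10))
        x = Z[:, 3] / np.linalg.norm(Z[:, 3])
        y = learning.compute_responses(x[:, None], Z / np.linalg.norm(Z[:, 3]))
        assert y[0, 3] == pytest.approx(1.0)

    def test_matches_bruteforce_loop(self, rng):
        W = rng.standard_normal((7, 3))
        Z = rng.standard_normal((7, 11))
        Y = learning.compute_responses(W, Z)
        for i in range(3):
            for t in range(11):
                assert Y[i, t] == pytest.approx(np.dot(W[:, i], Z[:, t]), abs=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            learning.compute_responses(rng.standard_normal((4, 2)), rng.standard_normal((5, 6)))


class TestSustainedObjective:
    def test_constant_energy_gives_one(self):
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=5.0, frame_ms=5.0)
        assert learning.sustained_objective(np.array([[1.0, -1.0, 1.0, -1.0]]), cfg) == pytest.approx(1.0)

    def test_alternating_energy_gives_zero(self):
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=5.0, frame_ms=5.0)
        y = np.array([[np.sqrt(2), 0.0, np.sqrt(2), 0.0]])
        assert learning.sustained_objective(y, cfg) == pytest.approx(0.0)

    def test_matches_triple_loop(self, rng):
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=15.0, frame_ms=5.0)
        Y = rng.standard_normal((4, 30))
        expected = 0.0
        for i in range(4):
            for n in (1, 2, 3):
                w = (3 - n + 1) / 3
                acc = [Y[i, t] ** 2 * Y[i, t - n] ** 2 for t in range(n, 30)]
                expected += w * np.mean(acc)
        assert learning.sustained_objective(Y, cfg) == pytest.approx(expected, abs=1e-12)

    def test_too_short_errors(self):
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=25.0, frame_ms=5.0)
        with pytest.raises(ValueError):
            learning.sustained_objective(np.ones((1, 5)), cfg)

    def test_weights_linearly_decaying(self):
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=25.0, frame_ms=5.0)
        np.testing.assert_allclose(cfg.weights, [5 / 5, 4 / 5, 3 / 5, 2 / 5, 1 / 5])


class TestKurtosisObjective:
    def test_hand_cases(self):
        assert learning.kurtosis_objective(np.array([[1.0], [1.0], [-1.0], [-1.0]])) == pytest.approx(1.0)
        assert learning.kurtosis_objective(np.array([[3.0], [-1.0], [-1.0], [-1.0]])) == pytest.approx(21 / 9)

    def test_gaussian_population_near_three(self, rng):
        Y = rng.standard_normal((10_000, 20))
        assert learning.kurtosis_objective(Y) == pytest.approx(3.0, abs=0.1)

    def test_three_point_population_is_constant(self, rng):
        # the sample kurtosis of 3 mean-centered values is identically 1.5
        for _ in range(5):
            assert learning.kurtosis_objective(rng.standard_normal((3, 40))) == pytest.approx(1.5)

    def test_zero_variance_time_skipped(self):
        Y = np.array([[1.0, 2.0], [1.0, -2.0], [1.0, 1.0], [1.0, -1.0]])
        with pytest.warns(UserWarning):
            v = learning.kurtosis_objective(Y)
        assert np.isfinite(v)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_sustained_matches_fd(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((6, 40))
        B = rng.standard_normal((6, 3))
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=15.0, frame_ms=5.0)
        g = learning.sustained_gradient(B, Z, cfg)
        fd = fd_gradient(lambda Y: learning.sustained_objective(Y, cfg), B, Z)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-5

    @pytest.mark.parametrize("seed", range(5))
    def test_kurtosis_matches_fd(self, seed):
        rng = np.random.default_rng(seed)
        Z = rng.standard_normal((6, 40))
        B = rng.standard_normal((6, 4))  # K=4: smallest non-degenerate population
        g = learning.kurtosis_gradient(B, Z)
        fd = fd_gradient(learning.kurtosis_objective, B, Z)
        assert np.abs(g - fd).max() / np.abs(fd).max() < 1e-5

    def test_zero_responses_zero_gradient(self, rng):
        Z = rng.standard_normal((5, 30))
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=10.0, frame_ms=5.0)
        g = learning.sustained_gradient(np.zeros((5, 2)), Z, cfg)
        np.testing.assert_array_equal(g, 0)

    def test_sustained_gradient_permutation_equivariant(self, rng):
        Z = rng.standard_normal((6, 50))
        B = rng.standard_normal((6, 4))
        cfg = learning.ObjectiveConfig(kind="sustained", N_ms=10.0, frame_ms=5.0)
        perm = [2, 0, 3, 1]
        g = learning.sustained_gradient(B, Z, cfg)
        gp = learning.sustained_gradient(B[:, perm], Z, cfg)
        np.testing.assert_allclose(gp, g[:, perm], atol=1e-12)

    def test_kurtosis_duplicated_columns_scale(self, rng):
        Z = rng.standard_normal((5, 30))
        B = rng.standard_normal((5, 4))
        g1 = learning.kurtosis_gradient(B, Z)
        g2 = learning.kurtosis_gradient(B, np.hstack([Z, Z]))
        np.testing.assert_allclose(g2, g1, atol=1e-10)


class TestProcrustes:
    def test_idempotent_on_orthonormal(self, rng):
        Q = np.linalg.qr(rng.standard_normal((6, 3)))[0]
        np.testing.assert_allclose(learning.procrustes_project(Q), Q, atol=1e-12)

    def test_diagonal_closed_form(self):
        np.testing.assert_allclose(learning.procrustes_project(np.diag([2.0, 5.0])), np.eye(2), atol=1e-12)

    def test_beats_random_orthonormal(self, rng):
        A = rng.standard_normal((6, 3))
        P = learning.procrustes_project(A)
        d_opt = np.linalg.norm(A - P)
        for _ in range(1000):
            Q = np.linalg.qr(rng.standard_normal((6, 3)))[0]
            assert np.linalg.norm(A - Q) >= d_opt - 1e-12

    def test_rank_deficient_errors(self):
        A = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            learning.procrustes_project(A)


class TestFitEnsemble:
    @pytest.mark.parametrize("kind,mode", [("sustained", "response"), ("sustained", "shape"),
                                           ("sparse", "response"), ("sparse", "shape")])
    def test_monotone_ascent_and_constraint(self, kind, mode, rng):
        X = rng.standard_normal((10, 400))
        obj = learning.ObjectiveConfig(kind=kind, N_ms=25.0 if kind == "sustained" else 125.0)
        ens, tr = learning.fit_ensemble(X, K=4, objective=obj, mode=mode, seed=0, max_iter=15)
        diffs = np.diff(tr.objectives)
        assert np.all(diffs >= -1e-10)
        assert max(tr.residuals) < 1e-8

    def test_determinism(self, rng):
        X = rng.standard_normal((8, 300))
        obj = learning.ObjectiveConfig(kind="sustained", N_ms=25.0)
        e1, _ = learning.fit_ensemble(X, K=3, objective=obj, seed=42, max_iter=10)
        e2, _ = learning.fit_ensemble(X, K=3, objective=obj, seed=42, max_iter=10)
        np.testing.assert_array_equal(e1.filters, e2.filters)

    def test_response_mode_unit_variance(self):
        pm, _, _ = stimgen.gen_slow_latent_patches(12, 3000, 3, 9, mixing_seed=0)
        model = patches.fit_whitening(pm, var_fraction=1.0)
        Z = patches.apply_whitening(pm, model)
        obj = learning.ObjectiveConfig(kind="sustained", N_ms=25.0)
        ens, _ = learning.fit_ensemble(Z, K=3, objective=obj, seed=1, whitening=model, max_iter=20)
        Y = ens.strfs.T @ pm.X
        assert np.abs(Y.var(axis=1) - 1.0).max() < 1e-3

    def test_k_exceeding_dimension_errors(self, rng):
        with pytest.raises(ValueError):
            learning.fit_ensemble(rng.standard_normal((4, 100)), K=5)


class TestContribution:
    def test_scores_sum_to_objective(self, rng):
        Z = rng.standard_normal((8, 200))
        obj = learning.ObjectiveConfig(kind="sustained", N_ms=25.0)
        ens, _ = learning.fit_ensemble(Z, K=4, objective=obj, seed=0, max_iter=5)
        Y = learning.compute_responses(ens, Z)
        scores, order = learning.per_filter_contribution(ens, Y)
        assert scores.sum() == pytest.approx(learning.sustained_objective(Y, obj), abs=1e-10)
        assert np.all(scores >= 0)
        assert np.all(np.diff(scores[order]) <= 1e-12)

    def test_single_filter_is_whole_objective(self, rng):
        Y = rng.standard_normal((1, 100))
        obj = learning.ObjectiveConfig(kind="sustained", N_ms=10.0)
        cfgscores = learning._sustained_per_filter(Y, obj)
        assert cfgscores[0] == pytest.approx(learning.sustained_objective(Y, obj))

    def test_sign_flip_invariance(self, rng):
        Y = rng.standard_normal((3, 100))
        obj = learning.ObjectiveConfig(kind="sustained", N_ms=10.0)
        s1 = learning._sustained_per_filter(Y, obj)
        s2 = learning._sustained_per_filter(-Y, obj)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_sparse_unsupported(self, rng):
        Z = rng.standard_normal((6, 100))
        ens, _ = learning.fit_ensemble(Z, K=4, objective=learning.ObjectiveConfig(kind="sparse"), seed=0, max_iter=3)
        with pytest.raises(ValueError, match="sustained"):
            learning.per_filter_contribution(ens, learning.compute_responses(ens, Z))
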