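"""Localized LS-SVM: dual solve vs primal oracle, neighbour selection."""

import numpy as np
import pytest
from scipy.optimize import minimize

import vitalcast as vc
from vitalcast.lssvm import _gram


def primal_oracle_predict(X, y, gamma, sigma0, X_test):
    """Independent check: minimize the kernelized primal objective
    ½‖w‖² + (γ/2)Σeᵢ² numerically with a generic optimizer.

    By the representer property w = Σ cᵢ φ(xᵢ), so ‖w‖² = cᵀΩc and
    eᵢ = yᵢ − (Ωc)ᵢ − b; optimization runs over (c, b) with BFGS, never
    touching the dual linear system under test.
    """
    X = np.atleast_2d(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    Omega = _gram(X, X, sigma0)

    def objective(z):
        c, b = z[:n], z[n]
        e = y - Omega @ c - b
        val = 0.5 * c @ Omega @ c + 0.5 * gamma * e @ e
        grad = np.empty(n + 1)
        grad[:n] = Omega @ c - gamma * (Omega @ e)
        grad[n] = -gamma * e.sum()
        return val, grad

    def hessian(z):
        H = np.empty((n + 1, n + 1))
        H[:n, :n] = Omega + gamma * (Omega @ Omega)
        H[:n, n] = H[n, :n] = gamma * Omega.sum(axis=1)
        H[n, n] = gamma * n
        return H

    res = minimize(objective, np.zeros(n + 1), method="trust-exact",
                   jac=True, hess=hessian,
                   options={"gtol": 1e-13, "maxiter": 20000})
    c, b = res.x[:n], res.x[n]
    return _gram(np.atleast_2d(X_test), X, sigma0) @ c + b


class TestGaussianKernel:
    def test_self_similarity_is_one(self):
        x = np.array([1.0, -2.0, 0.5])
        assert vc.gaussian_kernel(x, x, 2.0) == 1.0

    def test_symmetry(self):
        a, b = np.array([1.0, 0.0]), np.array([0.3, -1.2])
        assert vc.gaussian_kernel(a, b, 1.5) == vc.gaussian_kernel(b, a, 1.5)

    def test_distance_sigma_sqrt2_gives_exp_minus_one(self):
        sigma0 = 0.7
        a = np.zeros(2)
        b = np.array([sigma0 * np.sqrt(2), 0.0])
        assert vc.gaussian_kernel(a, b, sigma0) == pytest.approx(np.exp(-1))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            vc.gaussian_kernel([1.0], [1.0, 2.0], 1.0)


class TestFitLsSvm:
    def test_single_point_constant_predictor(self):
        m = vc.fit_ls_svm([[0.0]], [5.0], gamma=3.0, sigma0=1.0)
        assert m.b == pytest.approx(5.0)
        assert m.alpha[0] == pytest.approx(0.0)
        assert m.predict([[99.0]])[0] == pytest.approx(5.0)

    def test_antisymmetric_two_point_problem(self):
        m = vc.fit_ls_svm([[-1.0], [1.0]], [-1.0, 1.0], gamma=7.0, sigma0=0.8)
        assert m.predict([[0.0]])[0] == pytest.approx(0.0, abs=1e-12)
        assert m.b == pytest.approx(0.0, abs=1e-12)

    def test_dual_feasibility_and_residual(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12)
        m = vc.fit_ls_svm(X, y, gamma=5.0, sigma0=2.0)
        assert abs(m.alpha.sum()) < 1e-8
        assert m.dual_residual(y) < 1e-8

    def test_residuals_recoverable_as_alpha_over_gamma(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((8, 2))
        y = rng.standard_normal(8)
        gamma = 3.5
        m = vc.fit_ls_svm(X, y, gamma=gamma, sigma0=1.0)
        e = y - m.predict(X)
        np.testing.assert_allclose(e, m.alpha / gamma, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_primal_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(2, 9)), int(rng.integers(1, 4))
        X = rng.standard_normal((n, d))
        y = rng.standard_normal(n)
        gamma = float(rng.uniform(0.5, 20))
        sigma0 = float(rng.uniform(0.5, 3))
        X_test = rng.standard_normal((4, d))
        dual = vc.fit_ls_svm(X, y, gamma, sigma0).predict(X_test)
        primal = primal_oracle_predict(X, y, gamma, sigma0, X_test)
        np.testing.assert_allclose(dual, primal, atol=1e-5)

    def test_interpolation_limit_as_gamma_grows(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((6, 2))
        y = rng.standard_normal(6)
        errs = []
        for gamma in (1e0, 1e2, 1e4, 1e6, 1e8):
            m = vc.fit_ls_svm(X, y, gamma=gamma, sigma0=1.5)
            errs.append(np.max(np.abs(m.predict(X) - y)))
        assert all(a >= b for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-4  # near-interpolation at gamma = 1e8

    def test_duplicate_points_still_solve(self):
        X = np.zeros((3, 2))
        m = vc.fit_ls_svm(X, [1.0, 1.0, 1.0], gamma=10.0, sigma0=1.0)
        assert m.predict([[0.0, 0.0]])[0] == pytest.approx(1.0, abs=1e-6)


class TestKnnSelect:
    def _pool(self, seed=0, n=30, d=3):
        rng = np.random.default_rng(seed)
        return vc.TrainingPool(rng.standard_normal((n, d)),
                               rng.standard_normal(n))

    def test_k_equals_n_selects_everything(self):
        pool = self._pool()
        sel = vc.knn_select(np.zeros(3), pool, k=pool.n)
        assert len(sel.indices) == pool.n
        assert sel.lam.sum() == pool.n

    def test_k_1_selects_the_closest_row(self):
        pool = self._pool(1)
        q = pool.X[17] + 1e-9
        sel = vc.knn_select(q, pool, k=1)
        assert list(sel.indices) == [17]
        assert sel.r_s == pytest.approx(0.0, abs=1e-6)

    def test_binary_lambda_matches_radius_criterion(self):
        pool = self._pool(2)
        sel = vc.knn_select(np.zeros(3), pool, k=10)
        from vitalcast.lssvm import _pool_distances
        dist = _pool_distances(np.zeros(3), pool, "euclidean")
        inside = dist <= sel.r_s + 1e-12
        assert np.all(sel.lam[sel.indices] == 1)
        assert np.all(dist[sel.indices] <= sel.r_s + 1e-12)
        assert inside.sum() >= 10  # ties may exceed k; selection stays at k

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_full_sort_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 40))
        pool = vc.TrainingPool(rng.standard_normal((n, 2)),
                               rng.standard_normal(n))
        q = rng.standard_normal(2)
        k = int(rng.integers(1, n + 1))
        sel = vc.knn_select(q, pool, k=k)
        from vitalcast.lssvm import _pool_distances
        dist = _pool_distances(q, pool, "euclidean")
        oracle = sorted(range(n), key=lambda i: (dist[i], i))[:k]
        assert sorted(oracle) == list(sel.indices)

    def test_ties_at_kth_distance_break_by_lowest_index(self):
        X = np.array([[0.0], [1.0], [-1.0], [2.0]])  # rows 1,2 tie at |1|
        pool = vc.TrainingPool(X, np.zeros(4))
        sel = vc.knn_select(np.array([0.0]), pool, k=2)
        assert list(sel.indices) == [0, 1]

    def test_k_beyond_pool_rejected(self):
        pool = self._pool()
        with pytest.raises(ValueError):
            vc.knn_select(np.zeros(3), pool, k=pool.n + 1)


class TestPredictLocal:
    def test_k_equals_n_reproduces_global_fit(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        pool = vc.TrainingPool(X, y)
        q = rng.standard_normal(3)
        hp = vc.Hyperparams(k=20, gamma=8.0, sigma0=1.7)
        local = vc.predict_local(q, pool, hp)
        g = vc.fit_ls_svm(pool.standardize(X), y, 8.0, 1.7)
        global_pred = g.predict(pool.standardize(q))[0]
        assert local == pytest.approx(global_pred, abs=1e-8)

    def test_k_1_returns_nearest_neighbour_target(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((15, 2))
        y = rng.standard_normal(15)
        pool = vc.TrainingPool(X, y)
        q = X[4] + 1e-6
        pred = vc.predict_local(q, pool, vc.Hyperparams(k=1, gamma=2.0))
        assert pred == pytest.approx(y[4])

    def test_constant_target_pool_predicts_the_constant(self):
        rng = np.random.default_rng(13)
        pool = vc.TrainingPool(rng.standard_normal((12, 2)), np.full(12, 3.3))
        pred = vc.predict_local(rng.standard_normal(2), pool,
                                vc.Hyperparams(k=5, gamma=4.0))
        assert pred == pytest.approx(3.3, abs=1e-9)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((25, 3))
        y = rng.standard_normal(25)
        q = rng.standard_normal(3)
        hp = vc.Hyperparams(k=7, gamma=5.0)
        p1 = vc.predict_local(q, vc.TrainingPool(X, y), hp)
        perm = rng.permutation(25)
        p2 = vc.predict_local(q, vc.TrainingPool(X[perm], y[perm]), hp)
        assert p1 == pytest.approx(p2, abs=1e-10)


class TestTuneHyperparameters:
    def _learnable_pool(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-2, 2, size=(n, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(n)
        return vc.TrainingPool(X, y)

    def test_single_point_grid_returned_unchanged(self):
        pool = self._learnable_pool()
        hp = vc.tune_hyperparameters(
            pool, grid={"k": [5], "gamma": [2.0], "sigma0": [1.0]}, folds=3)
        assert (hp.k, hp.gamma, hp.sigma0) == (5, 2.0, 1.0)

    def test_fixed_seed_deterministic_selection(self):
        pool = self._learnable_pool()
        grid = {"k": [5, 10], "gamma": [1.0, 10.0], "sigma0": [0.5, 2.0]}
        a = vc.tune_hyperparameters(pool, grid=grid, folds=3, seed=9)
        b = vc.tune_hyperparameters(pool, grid=grid, folds=3, seed=9)
        assert a == b

    def test_selected_bandwidth_beats_grid_extremes(self):
        """Exhaustive grid evaluation: the winning σ₀ must achieve CV error
        no worse than the extreme bandwidths of the same grid."""
        pool = self._learnable_pool(n=80, seed=5)
        sigmas = [0.01, 0.5, 1.0, 50.0]

        def cv_mae(sigma0, folds=4, seed=2):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(pool.n)
            fold_of = np.empty(pool.n, dtype=int)
            fold_of[perm] = np.arange(pool.n) % folds
            errs = []
            for f in range(folds):
                tr = fold_of != f
                sub = vc.TrainingPool(pool.X[tr], pool.y[tr])
                hp = vc.Hyperparams(k=10, gamma=10.0, sigma0=sigma0)
                for i in np.flatnonzero(~tr):
                    errs.append(abs(vc.predict_local(pool.X[i], sub, hp)
                                    - pool.y[i]))
            return np.mean(errs)

        hp = vc.tune_hyperparameters(
            pool, grid={"k": [10], "gamma": [10.0], "sigma0": sigmas},
            folds=4, seed=2)
        assert cv_mae(hp.sigma0) <= min(cv_mae(sigmas[0]), cv_mae(sigmas[-1]))

    def test_folds_exceeding_pool_rejected(self):
        pool = self._learnable_pool(n=5)
        with pytest.raises(ValueError):
            vc.tune_hyperparameters(pool, folds=9)
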