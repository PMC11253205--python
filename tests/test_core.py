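"""SVR core: residualization, dual fit, backprojection, hyperopt, CV maps."""

import numpy as np
import pytest

from svrlsm.core import (
    KernelCache,
    SvrLsmConfig,
    beta_map,
    crossval_beta,
    fit_svr,
    make_contrast,
    optimize_hyperparameters,
    residualize_volume,
    zscore_map,
)

from _oracles import (
    best_dual_on_lattice,
    ols_residuals_2x2,
    primal_linear_svr,
    svr_dual_objective,
)


class TestResidualization:
    def test_residuals_uncorrelated_with_volume(self, rng):
        X = (rng.random((30, 20)) < 0.3).astype(float)
        y = rng.integers(0, 2, 30).astype(float)
        v = rng.lognormal(3.0, 0.5, 30)
        Xr, yr = residualize_volume(X, y, v)
        vc = v - v.mean()
        assert np.abs(Xr.T @ vc / 30).max() < 1e-8
        assert abs(yr @ vc / 30) < 1e-8

    def test_idempotence(self, rng):
        X = rng.standard_normal((15, 6))
        y = rng.standard_normal(15)
        v = rng.lognormal(2.0, 0.4, 15)
        X1, y1 = residualize_volume(X, y, v)
        X2, y2 = residualize_volume(X1, y1, v)
        np.testing.assert_allclose(X2, X1, atol=1e-10)
        np.testing.assert_allclose(y2, y1, atol=1e-10)

    def test_collinear_outcome_annihilated(self, rng):
        X = rng.standard_normal((12, 4))
        v = rng.lognormal(2.0, 0.4, 12)
        _, yr = residualize_volume(X, 2.0 * v, v)
        np.testing.assert_allclose(yr, 0.0, atol=1e-10)

    def test_constant_volume_degenerates_to_centering(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        v = np.full(10, 5.0)
        with pytest.warns(UserWarning, match="constant"):
            Xr, yr = residualize_volume(X, y, v)
        np.testing.assert_allclose(Xr, X - X.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(yr, y - y.mean(), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((8, 5))
        y = rng.standard_normal(8)
        v = rng.lognormal(1.0, 0.6, 8)
        Xr, yr = residualize_volume(X, y, v)
        Xo, yo = ols_residuals_2x2(X, y, v)
        np.testing.assert_allclose(Xr, Xo, atol=1e-10)
        np.testing.assert_allclose(yr, yo, atol=1e-10)

    def test_volume_scale_invariance(self, rng):
        X = rng.standard_normal((20, 7))
        y = rng.standard_normal(20)
        v = rng.lognormal(2.0, 0.5, 20)
        Xr1, yr1 = residualize_volume(X, y, v)
        Xr2, yr2 = residualize_volume(X, y, 3.7 * v)
        np.testing.assert_allclose(Xr1, Xr2, atol=1e-9)
        np.testing.assert_allclose(yr1, yr2, atol=1e-9)

    def test_nonpositive_volumes_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        with pytest.raises(ValueError):
            residualize_volume(X, np.ones(5), np.array([1.0, 2, 3, 0, 5]))


class TestFitSvr:
    def test_constant_target_inside_tube_gives_null_model(self, rng):
        X = rng.standard_normal((8, 4))
        y = np.full(8, 0.05)  # within epsilon=0.1 of its mean
        model = fit_svr(X, y, C=1.0, gamma=0.5, epsilon=0.1)
        assert len(model.alpha) == 0 or np.allclose(model.alpha, 0.0)
        np.testing.assert_allclose(model.predict(X), model.bias, atol=1e-9)

    def test_dual_solution_beats_coarse_lattice(self, rng):
        X = rng.standard_normal((4, 3))
        y = rng.standard_normal(4)
        C, eps, gamma = 1.0, 0.1, 0.5
        model = fit_svr(X, y, C=C, gamma=gamma, epsilon=eps, tol=1e-10)
        K = KernelCache(X).gram("rbf", gamma)
        alpha_full = np.zeros(4)
        alpha_full[model.support] = model.alpha
        attained = svr_dual_objective(alpha_full, K, y, eps)
        lattice_best = best_dual_on_lattice(K, y, C, eps, steps=9)
        assert attained >= lattice_best - 1e-3
        # feasibility of the returned coefficients
        assert abs(alpha_full.sum()) < 1e-8
        assert np.abs(alpha_full).max() <= C + 1e-8

    def test_duplicating_inactive_subject_keeps_predictions(self, rng):
        # a subject strictly inside the epsilon tube has alpha = 0;
        # duplicating it must leave the fitted function unchanged
        X = rng.standard_normal((10, 5))
        y = rng.standard_normal(10) * 0.5
        eps = 0.5
        model = fit_svr(X, y, C=10.0, gamma=0.3, epsilon=eps, tol=1e-10)
        resid = np.abs(model.predict(X) - y)
        inactive = np.setdiff1d(np.arange(10), model.support)
        inside = [i for i in inactive if resid[i] < 0.9 * eps]
        assert inside, "fixture must contain a strictly inactive subject"
        i = inside[0]
        X2 = np.vstack([X, X[i]])
        y2 = np.append(y, y[i])
        model2 = fit_svr(X2, y2, C=10.0, gamma=0.3, epsilon=eps, tol=1e-10)
        grid = rng.standard_normal((20, 5))
        np.testing.assert_allclose(
            model.predict(grid), model2.predict(grid), atol=1e-6
        )

    def test_nonfinite_inputs_rejected(self, rng):
        X = rng.standard_normal((5, 3))
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            fit_svr(X, np.ones(5), C=1.0, gamma=0.1)


class TestBetaMap:
    def test_null_model_gives_zero_map(self, rng):
        X = rng.standard_normal((6, 4))
        model = fit_svr(X, np.zeros(6), C=1.0, gamma=0.5, epsilon=0.1)
        np.testing.assert_allclose(beta_map(model, X), 0.0)

    def test_linear_kernel_equals_primal_weights(self, rng):
        for _ in range(5):
            X = rng.standard_normal((10, 8))
            y = rng.standard_normal(10)
            model = fit_svr(X, y, C=2.0, epsilon=0.1, kernel="linear", tol=1e-10)
            w, _b = primal_linear_svr(X, y, C=2.0, epsilon=0.1)
            np.testing.assert_allclose(beta_map(model, X), w, atol=1e-6)

    def test_column_permutation_equivariance(self, rng):
        X = rng.standard_normal((12, 6))
        y = rng.standard_normal(12)
        perm = rng.permutation(6)
        m1 = fit_svr(X, y, C=1.0, gamma=0.2, epsilon=0.1)
        m2 = fit_svr(X[:, perm], y, C=1.0, gamma=0.2, epsilon=0.1)
        np.testing.assert_allclose(
            beta_map(m1, X)[perm], beta_map(m2, X[:, perm]), atol=1e-8
        )

    def test_label_flip_antisymmetry(self, rng):
        X = rng.standard_normal((15, 10))
        y = rng.standard_normal(15)
        m_pos = fit_svr(X, y, C=5.0, gamma=0.2, epsilon=0.1, tol=1e-10)
        m_neg = fit_svr(X, -y, C=5.0, gamma=0.2, epsilon=0.1, tol=1e-10)
        np.testing.assert_allclose(
            beta_map(m_pos, X), -beta_map(m_neg, X), atol=1e-6
        )


@pytest.fixture(scope="module")
def toy_problem():
    rng = np.random.default_rng(77)
    X = rng.standard_normal((30, 5))
    w = np.array([1.0, -0.5, 0.0, 0.8, 0.0])
    y = np.tanh(X @ w) + 0.1 * rng.standard_normal(30)
    return X, y


class TestHyperopt:
    def test_seeded_determinism(self, toy_problem):
        X, y = toy_problem
        a = optimize_hyperparameters(X, y, iterations=12, seed=3)
        b = optimize_hyperparameters(X, y, iterations=12, seed=3)
        assert a == b

    def test_best_point_within_bounds(self, toy_problem):
        X, y = toy_problem
        bounds = ((1e-2, 1e2), (1e-3, 1e1))
        C, gamma = optimize_hyperparameters(X, y, iterations=15, bounds=bounds,
                                            seed=1)
        assert 1e-2 <= C <= 1e2
        assert 1e-3 <= gamma <= 1e1

    def test_beats_coarse_grid_within_5pct(self, toy_problem):
        X, y = toy_problem
        from svrlsm.core import _cv_mse, _make_folds

        cache = KernelCache(X)
        folds = _make_folds(len(y), 5, 4, None)
        (C, gamma), trace = optimize_hyperparameters(
            X, y, iterations=40, seed=4, cache=cache, return_trace=True
        )
        loss_star = _cv_mse(X, y, C, gamma, 0.1, folds, cache, "rbf")
        grid = [
            _cv_mse(X, y, 10.0**lc, 10.0**lg, 0.1, folds, cache, "rbf")
            for lc in np.linspace(-3, 3, 10)
            for lg in np.linspace(-3, 3, 10)
        ]
        assert loss_star <= min(grid) * 1.05

    def test_degenerate_bounds_rejected(self, toy_problem):
        X, y = toy_problem
        with pytest.raises(ValueError):
            optimize_hyperparameters(X, y, iterations=10,
                                     bounds=((1.0, 1.0), (1e-3, 1e3)))


class TestCrossvalBeta:
    @pytest.fixture()
    def setup(self, rng):
        X = (rng.random((25, 40)) < 0.3).astype(float)
        y = np.zeros(25)
        y[:10] = 1.0
        cfg = SvrLsmConfig(C=30.0, gamma=5.0, cv_folds=5,
                           hyperopt_iterations=10)
        return X, y, cfg

    def test_fold_average_matches_recomputation(self, setup):
        X, y, cfg = setup
        bm = crossval_beta(X, y, cfg, C=30.0, gamma=5.0,
                           strata=y.astype(int), keep_folds=True)
        np.testing.assert_allclose(bm.beta, bm.fold_betas.mean(axis=0),
                                   atol=1e-12)

    def test_partition_covers_every_subject_once(self, setup):
        X, y, cfg = setup
        from svrlsm.core import _make_folds

        folds = _make_folds(25, 5, cfg.seed, y.astype(int))
        tests = np.concatenate([te for _, te in folds])
        assert sorted(tests) == list(range(25))

    def test_determinism(self, setup):
        X, y, cfg = setup
        a = crossval_beta(X, y, cfg, C=30.0, gamma=5.0, strata=y.astype(int))
        b = crossval_beta(X, y, cfg, C=30.0, gamma=5.0, strata=y.astype(int))
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_single_class_fold_reshuffles_then_errors(self, setup):
        X, y, cfg = setup
        y2 = np.zeros(25)
        y2[0] = 1.0  # one positive: every split has single-class train folds
        with pytest.warns(UserWarning, match="reshuffling"):
            with pytest.raises(ValueError, match="both outcome classes"):
                crossval_beta(X, y2, cfg, C=30.0, gamma=5.0,
                              strata=y2.astype(int))


class TestZScore:
    def test_standardization_arithmetic(self):
        np.testing.assert_allclose(zscore_map(np.array([1.0, 2.0, 3.0])),
                                   [-1.0, 0.0, 1.0])

    def test_constant_map_is_zero(self):
        np.testing.assert_allclose(zscore_map(np.full(5, 3.3)), 0.0)

    def test_mean_zero_sd_one(self, rng):
        z = zscore_map(rng.standard_normal(200))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestContrast:
    def test_one_vs_rest_coding(self):
        subtypes = np.array(["MES", "RTK I", "MES", "other"], dtype=object)
        c = make_contrast(subtypes, "MES")
        np.testing.assert_array_equal(c.y, [1.0, 0.0, 1.0, 0.0])

    def test_absent_subtype_rejected(self):
        with pytest.raises(ValueError):
            make_contrast(np.array(["A", "B"], dtype=object), "C")
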