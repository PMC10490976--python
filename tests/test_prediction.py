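"""Tests for the split rule, regression, mirroring, likelihood, and the
Levenberg-Marquardt-trained network."""

import math

import numpy as np
import pytest

import cornvec as cv


class TestSplit:
    @pytest.mark.parametrize("n, sizes", [(88, (62, 13, 13)), (10, (7, 2, 1)), (3, (2, 1, 0))])
    def test_split_sizes(self, n, sizes):
        sp = cv.split_dataset(n, seed=0)
        assert (len(sp.train), len(sp.val), len(sp.test)) == sizes

    def test_disjoint_union_and_determinism(self):
        for n in (5, 17, 88, 101):
            sp = cv.split_dataset(n, seed=9)
            allidx = np.concatenate([sp.train, sp.val, sp.test])
            assert sorted(allidx) == list(range(n))
            sp2 = cv.split_dataset(n, seed=9)
            assert np.array_equal(sp.train, sp2.train)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            cv.split_dataset(2)


class TestMeanSquaredPE:
    def test_values(self):
        y = np.array([[1.0, 2.0]])
        assert cv.mean_squared_pe(y, y) == 0.0
        assert cv.mean_squared_pe(np.array([[0.0, 0.0]]), np.array([[1.0, 1.0]])) == 1.0
        pred = np.zeros((2, 2))
        obs = np.array([[1.0, 0.0], [0.0, 2.0]])
        assert cv.mean_squared_pe(pred, obs) == pytest.approx(1.25)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cv.mean_squared_pe(np.empty((0, 2)), np.empty((0, 2)))


class TestRegression:
    def test_noiseless_parameter_recovery(self):
        rng = np.random.default_rng(0)
        A = np.array([[0.9, -0.05], [0.01, 0.7]])
        b = np.array([-0.18, -0.02])
        X = rng.normal(0, 1.5, size=(50, 2))
        Y = X @ A.T + b
        m = cv.fit_multivariate_regression(X, Y)
        assert np.abs(m.matrix - A).max() < 1e-8
        assert np.abs(m.intercept - b).max() < 1e-8
        assert m.logL is None  # perfect fit: degenerate likelihood

    def test_noisy_recovery_bias_shrinks_at_large_n(self):
        rng = np.random.default_rng(1)
        A = np.array([[0.9, -0.05], [0.01, 0.7]])
        b = np.array([-0.18, -0.02])
        X = rng.normal(0, 1.5, size=(10_000, 2))
        Y = X @ A.T + b + rng.normal(0, 0.3, size=(10_000, 2))
        m = cv.fit_multivariate_regression(X, Y)
        assert np.abs(m.matrix - A).max() < 0.02
        assert np.abs(m.intercept - b).max() < 0.02

    def test_zero_inputs_intercept_is_column_mean(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(20, 2))
        X = np.zeros((20, 2))
        with pytest.warns(UserWarning, match="rank-deficient"):
            m = cv.fit_multivariate_regression(X, Y)
        assert m.intercept == pytest.approx(Y.mean(axis=0), abs=1e-10)
        assert m.matrix == pytest.approx(np.zeros((2, 2)), abs=1e-10)

    def test_matches_statsmodels_ols(self, kerat_to_real_arrays):
        sm = pytest.importorskip("statsmodels.api")
        X, Y = kerat_to_real_arrays
        m = cv.fit_multivariate_regression(X, Y)
        design = sm.add_constant(X)
        for j in range(2):
            res = sm.OLS(Y[:, j], design).fit()
            assert m.intercept[j] == pytest.approx(res.params[0], abs=1e-8)
            assert m.matrix[j] == pytest.approx(res.params[1:], abs=1e-8)

    def test_robust_fit_downweights_outliers(self):
        rng = np.random.default_rng(3)
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        X = rng.normal(size=(200, 2))
        Y = X @ A.T + rng.normal(0, 0.05, size=(200, 2))
        Y[:10] += 25.0  # gross outliers
        plain = cv.fit_multivariate_regression(X, Y)
        robust = cv.fit_multivariate_regression(X, Y, robust=True)
        assert np.abs(robust.matrix - A).max() < np.abs(plain.matrix - A).max()
        assert np.abs(robust.matrix - A).max() < 0.02


class TestMirrorModel:
    def test_published_od_to_os(self):
        m = cv.load_published_models()["IOLM"]
        os_m = cv.mirror_model_for_eye(m)
        assert os_m.eye_side == "OS"
        assert os_m.matrix == pytest.approx(np.array([[0.9150, 0.0472], [0.0018, 0.6952]]))
        assert os_m.intercept == pytest.approx(np.array([-0.1823, 0.0229]))

    def test_involution_and_fixed_points(self):
        m = cv.RegressionModel(np.array([[0.9, 0.1], [-0.2, 0.7]]), np.array([0.1, -0.3]))
        back = cv.mirror_model_for_eye(cv.mirror_model_for_eye(m))
        assert np.array_equal(back.matrix, m.matrix)
        assert np.array_equal(back.intercept, m.intercept)
        diag = cv.RegressionModel(np.diag([0.9, 0.7]), np.array([0.5, 0.0]))
        mirrored = cv.mirror_model_for_eye(diag)
        assert np.array_equal(mirrored.matrix, diag.matrix)
        assert np.array_equal(mirrored.intercept, diag.intercept)

    def test_od_os_equivariance(self):
        """apply(mirror(m), mirror(x)) == mirror(apply(m, x)) exactly."""
        m = cv.RegressionModel(np.array([[0.91, -0.05], [-0.002, 0.7]]), np.array([-0.18, -0.02]))
        rng = np.random.default_rng(4)
        for x in rng.normal(size=(20, 2)):
            lhs = cv.apply_regression(cv.mirror_model_for_eye(m), x * [1, -1])
            rhs = cv.apply_regression(m, x) * [1, -1]
            assert lhs == pytest.approx(rhs, abs=1e-15)


class TestApplyRegression:
    def test_published_intercept_and_unit_input(self):
        m = cv.load_published_models()["IOLM"]
        assert cv.apply_regression(m, np.zeros(2)) == pytest.approx([-0.1823, -0.0229])
        assert cv.apply_regression(m, np.array([1.0, 0.0])) == pytest.approx(
            [0.7327, -0.0247]
        )

    def test_identity_model(self):
        m = cv.RegressionModel(np.eye(2), np.zeros(2))
        x = np.array([0.7, -0.3])
        assert cv.apply_regression(m, x) == pytest.approx(x)


class TestGaussianLogLikelihood:
    def test_perfect_fit_is_degenerate(self):
        m = cv.RegressionModel(np.eye(2), np.zeros(2))
        X = np.random.default_rng(5).normal(size=(10, 2))
        with pytest.raises(cv.DegenerateLikelihoodError):
            cv.gaussian_log_likelihood(m, X, X)

    def test_closed_form_with_unit_ml_covariance(self):
        # residuals R with R'R = 3 I, so the ML covariance is the identity
        R = np.array([[math.sqrt(3), 0.0], [0.0, math.sqrt(3)], [0.0, 0.0]])
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        m = cv.RegressionModel(np.eye(2), np.zeros(2))
        val = cv.gaussian_log_likelihood(m, X, X + R)
        assert val == pytest.approx(-1.5 * (2.0 * math.log(2.0 * math.pi) + 2.0))

    def test_scaling_residuals_up_decreases_loglik(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        R = rng.normal(size=(30, 2))
        m = cv.RegressionModel(np.eye(2), np.zeros(2))
        assert cv.gaussian_log_likelihood(m, X, X + 10 * R) < cv.gaussian_log_likelihood(
            m, X, X + R
        )


class TestNetwork:
    def test_init_reproducible_and_shapes(self):
        a = cv.init_network(seed=7)
        b = cv.init_network(seed=7)
        c = cv.init_network(seed=8)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)
        assert any(not np.array_equal(wa, wc) for wa, wc in zip(a.weights, c.weights))
        out = cv.network_forward(a, np.zeros((5, 2)))
        assert out.shape == (5, 2)

    def test_zero_network_outputs_its_biases(self):
        net = cv.init_network(seed=0)
        net.weights = [np.zeros_like(w) for w in net.weights]
        net.biases[-1] = np.array([0.3, -0.4])
        out = cv.network_forward(net, np.array([[1.2, -0.7]]))
        assert out[0] == pytest.approx([0.3, -0.4])

    def test_zero_targets_objective_collapses(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(40, 2))
        Y = np.zeros((40, 2))
        sp = cv.split_dataset(40, seed=1)
        net = cv.train_network_lm(cv.init_network(seed=1), X, Y, sp, max_epochs=100)
        pred = cv.network_forward(net, X[sp.train])
        assert cv.mean_squared_pe(pred, Y[sp.train]) < 1e-6

    def test_accepted_steps_never_increase_training_objective(self, kerat_to_real_arrays):
        X, Y = kerat_to_real_arrays
        sp = cv.split_dataset(len(X), seed=3)
        net = cv.train_network_lm(cv.init_network(seed=3), X, Y, sp, max_epochs=60)
        train_curve = net.history[:, 0]
        assert len(train_curve) >= 1
        assert np.all(np.diff(train_curve) <= 1e-15)

    def test_early_stopping_returns_validation_optimal_epoch(self, kerat_to_real_arrays):
        X, Y = kerat_to_real_arrays
        sp = cv.split_dataset(len(X), seed=3)
        net = cv.train_network_lm(cv.init_network(seed=3), X, Y, sp, max_epochs=60)
        val_curve = net.history[:, 1]
        assert net.best_epoch == int(np.argmin(val_curve)) + 1
        # returned weights reproduce the best validation objective
        pred = cv.network_forward(net, X[sp.val])
        assert cv.mean_squared_pe(pred, Y[sp.val]) == pytest.approx(
            val_curve.min(), rel=1e-9
        )

    def test_linear_teacher_network_matches_regression(self):
        """On linear synthetic data the network (which contains linear maps)
        reaches a test objective within 10% of the regression's."""
        teacher = cv.LinearTeacher(
            matrix=((0.92, -0.05), (-0.01, 0.70)), intercept=(-0.18, -0.02),
            residual_sd=0.10,
        )
        cfg = cv.SyntheticConfig(n_eyes=1000, seed=17, both_eyes_fraction=0.0, teacher=teacher)
        records, _ = cv.generate_cohort(cfg)
        panel = cv.decompose_cohort(records)
        X = panel.frame[["IOLM_keratometric_C0", "IOLM_keratometric_C45"]].to_numpy()
        Y = panel.frame[["CASIA_post_total_C0", "CASIA_post_total_C45"]].to_numpy()
        sp = cv.split_dataset(len(X), seed=17)
        reg = cv.fit_multivariate_regression(X[sp.train], Y[sp.train])
        net = cv.train_network_lm(cv.init_network(seed=17), X, Y, sp, max_epochs=200)
        reg_obj = cv.mean_squared_pe(cv.apply_regression(reg, X[sp.test]), Y[sp.test])
        net_obj = cv.mean_squared_pe(cv.network_forward(net, X[sp.test]), Y[sp.test])
        assert net_obj <= 1.1 * reg_obj

    def test_disjointness_enforced(self, kerat_to_real_arrays):
        X, Y = kerat_to_real_arrays
        bad = cv.SplitIndices(np.array([0, 1, 2, 3]), np.array([3, 4]), np.array([5]))
        with pytest.raises(ValueError, match="disjoint"):
            cv.train_network_lm(cv.init_network(), X, Y, bad)


class TestPredictionErrorStats:
    def test_perfect_and_unbiased_models(self):
        rng = np.random.default_rng(21)
        A = np.array([[0.9, 0.0], [0.0, 0.7]])
        b = np.array([-0.1, 0.05])
        X = rng.normal(size=(60, 2))
        Y = X @ A.T + b
        perfect = cv.RegressionModel(A, b)
        stats_ = cv.prediction_error_stats({"reg": perfect}, X, Y)
        assert stats_["reg"]["summary"]["C0"].mean == pytest.approx(0.0, abs=1e-12)
        assert stats_["reg"]["summary"]["C45"].sd == pytest.approx(0.0, abs=1e-12)
        assert stats_["reg"]["ellipse"] is None  # degenerate error cloud

    def test_fitted_model_has_zero_mean_error_on_training_data(self, kerat_to_real_arrays):
        X, Y = kerat_to_real_arrays
        m = cv.fit_multivariate_regression(X, Y)
        stats_ = cv.prediction_error_stats({"reg": m}, X, Y)
        for comp in ("C0", "C45"):
            s = stats_["reg"]["summary"][comp]
            assert abs(s.mean) < 3 * s.sd / math.sqrt(s.n) + 1e-12
        assert stats_["reg"]["ellipse"] is not None
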