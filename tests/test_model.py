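"""The nonlinear MVAR estimator: forward map, Taylor separation, the
connectivity measures, order selection, and the training protocol."""

import numpy as np
import pytest

from ncreann.model import (NMVARModel, TrainingConfig, build_lag_matrix,
                           estimate_connectivity, fit_nmvar,
                           linear_connectivity, nonlinear_connectivity,
                           select_model_order, taylor_linear_part)
from ncreann.synthetic import (CoupledSystemSpec, NonlinearTerm,
                               simulate_nmvar)


def _hand_model(W1, b1, W2, b2, p=1, activation="tanh"):
    W1, b1, W2, b2 = map(lambda a: np.asarray(a, float), (W1, b1, W2, b2))
    m = W2.shape[0]
    return NMVARModel(W_in=W1, b_hidden=b1, W_out=W2, b_out=b2, order=p,
                      activation=activation,
                      channel_means=np.zeros(m), channel_sds=np.ones(m),
                      channel_names=[f"c{i}" for i in range(m)])


class TestPredict:
    def test_zero_weights_zero_biases_give_zero(self):
        model = _hand_model(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)),
                            np.zeros(2))
        assert np.allclose(model.predict(np.array([1.0, -2.0])), 0.0)

    def test_hand_built_network_matches_manual_arithmetic(self):
        W1 = [[0.2, -0.1], [0.3, 0.4]]
        b1 = [0.1, -0.2]
        W2 = [[1.0, 0.5], [-0.3, 0.8]]
        b2 = [0.05, -0.05]
        model = _hand_model(W1, b1, W2, b2)
        x = np.array([0.7, -0.4])
        h = np.tanh(np.array(W1) @ x + b1)
        expected = np.array(W2) @ h + b2
        assert np.allclose(model.predict(x), expected)

    def test_linear_activation_satisfies_superposition(self, rng):
        model = _hand_model(rng.normal(size=(3, 4)), rng.normal(size=3),
                            rng.normal(size=(2, 3)), np.zeros(2), p=2,
                            activation="linear")
        x, y = rng.normal(size=4), rng.normal(size=4)
        lhs = model.predict(x + y)
        rhs = model.predict(x) + model.predict(y) - model.predict(np.zeros(4))
        assert np.allclose(lhs, rhs)

    def test_wrong_lag_vector_length_rejected(self):
        model = _hand_model(np.zeros((2, 2)), np.zeros(2), np.zeros((2, 2)),
                            np.zeros(2))
        with pytest.raises(ValueError, match="length"):
            model.predict(np.zeros(3))


class TestTaylorSeparation:
    def test_zero_output_weights_give_zero_tensor(self):
        model = _hand_model(np.ones((2, 2)), np.ones(2), np.zeros((2, 2)),
                            np.zeros(2))
        assert np.allclose(taylor_linear_part(model), 0.0)

    def test_hand_computed_jacobian(self, rng):
        W1 = rng.normal(size=(2, 2))
        b1 = rng.normal(size=2)
        W2 = rng.normal(size=(2, 2))
        model = _hand_model(W1, b1, W2, np.zeros(2))
        sech2 = 1.0 - np.tanh(b1) ** 2  # d tanh / dx at the bias
        expected = W2 @ np.diag(sech2) @ W1
        assert np.allclose(taylor_linear_part(model)[:, :, 0], expected)

    def test_linear_activation_taylor_reproduces_full_map(self, rng):
        model = _hand_model(rng.normal(size=(4, 6)), rng.normal(size=4),
                            rng.normal(size=(3, 4)), rng.normal(size=3),
                            p=2, activation="linear")
        A = taylor_linear_part(model)
        X = rng.normal(size=(20, 6))
        J = np.hstack([A[:, :, k] for k in range(2)])
        f0 = model.predict(np.zeros(6))
        assert np.allclose(model.forward_batch(X), f0 + X @ J.T)

    def test_lc_is_mean_of_absolute_coefficients_over_lags(self):
        # single coefficient 0.4 at lag 1 of pair 0 -> 1, order 2:
        # lC = mean(|0.4|, 0) = 0.2
        W1 = np.zeros((1, 4))
        W1[0, 0] = 0.4  # source channel 0, lag 1
        W2 = np.array([[0.0], [1.0]])
        model = _hand_model(W1, np.zeros(1), W2, np.zeros(2), p=2,
                            activation="linear")
        lc = linear_connectivity(model)
        assert lc[0, 1] == pytest.approx(0.2)
        assert np.all(lc >= 0)


class TestLagMatrix:
    def test_lag_major_ordering_and_no_trial_straddling(self):
        data = np.arange(2 * 2 * 5, dtype=float).reshape(2, 2, 5)
        X, Y = build_lag_matrix(data, 2)
        assert X.shape == (6, 4) and Y.shape == (6, 2)
        # first row of trial 0: [x0(1), x1(1), x0(0), x1(0)]
        assert list(X[0]) == [1.0, 6.0, 0.0, 5.0]
        assert list(Y[0]) == [2.0, 7.0]
        # first row of trial 1 uses only trial-1 samples
        assert list(X[3]) == [11.0, 16.0, 10.0, 15.0]


class TestOrderSelection:
    def _var2(self, seed, t=5000):
        coeffs = np.zeros((2, 2, 2))
        coeffs[0, 0, 0], coeffs[1, 1, 0] = 0.4, 0.3
        coeffs[1, 0, 1] = 0.35  # lag-2 structure forces order 2
        coeffs[0, 0, 1] = -0.3
        return simulate_nmvar(CoupledSystemSpec(
            n_channels=2, order=2, linear_coeffs=coeffs, noise_sd=1.0,
            samples_per_trial=t, seed=seed))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_var2_data_selects_order_2(self, seed):
        assert select_model_order(self._var2(seed), range(1, 6)) == 2

    def test_white_noise_selects_minimum_candidate(self, rng):
        data = rng.standard_normal((1, 2, 3000))
        assert select_model_order(data, range(1, 6)) == 1

    def test_agrees_with_statsmodels_bic(self):
        sm = pytest.importorskip("statsmodels.tsa.api")
        ep = self._var2(5)
        ours = select_model_order(ep, range(1, 6))
        theirs = sm.VAR(ep.data[0].T).select_order(maxlags=5).bic
        assert ours == theirs == 2

    def test_too_long_candidates_skipped_with_warning(self, rng):
        data = rng.standard_normal((1, 2, 30))
        with pytest.warns(UserWarning, match="skipped"):
            p = select_model_order(data, [1, 2, 25])
        assert p in (1, 2)


class TestFitting:
    def test_high_snr_var_reaches_high_test_r2(self):
        coeffs = np.zeros((2, 2, 1))
        coeffs[0, 0, 0], coeffs[1, 1, 0] = 0.96, 0.96
        coeffs[1, 0, 0] = 0.1
        ep = simulate_nmvar(CoupledSystemSpec(
            n_channels=2, order=1, linear_coeffs=coeffs, noise_sd=1.0,
            samples_per_trial=2000, seed=7))
        _, metrics = fit_nmvar(ep, TrainingConfig(seed=7), 1)
        assert metrics.r2_test > 0.9

    def test_white_noise_gives_near_zero_test_r2(self, rng):
        data = rng.standard_normal((1, 2, 1500))
        _, metrics = fit_nmvar(data, TrainingConfig(seed=3), 1)
        assert abs(metrics.r2_test) < 0.1

    def test_fold_to_fold_r2_dispersion_small(self):
        coeffs = np.zeros((2, 2, 1))
        coeffs[0, 0, 0], coeffs[1, 1, 0] = 0.8, 0.7
        ep = simulate_nmvar(CoupledSystemSpec(
            n_channels=2, order=1, linear_coeffs=coeffs, noise_sd=1.0,
            samples_per_trial=1500, seed=2))
        _, metrics = fit_nmvar(ep, TrainingConfig(seed=2), 1)
        folds = [f["r2_test"] for f in metrics.per_fold]
        assert len(folds) == 5 and np.std(folds) < 0.1

    def test_reproducible_given_seed(self, var1_spec):
        ep = simulate_nmvar(var1_spec)
        cfg = TrainingConfig(seed=5, compute_cv=False, max_epochs=30)
        m1, _ = fit_nmvar(ep, cfg, 1)
        m2, _ = fit_nmvar(ep, cfg, 1)
        assert np.array_equal(m1.W_in, m2.W_in)

    def test_divergent_learning_rate_fails_with_diagnostics(self, var1_spec):
        ep = simulate_nmvar(var1_spec)
        cfg = TrainingConfig(activation="linear", learning_rate=100.0,
                             seed=0, compute_cv=False)
        with pytest.raises(RuntimeError, match="diverged"):
            fit_nmvar(ep, cfg, 1)

    def test_constant_channel_rejected(self):
        data = np.zeros((1, 2, 100))
        with pytest.raises(ValueError, match="standardize"):
            fit_nmvar(data, TrainingConfig(), 1)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrainingConfig(split=(0.7, 0.2, 0.2))
        with pytest.raises(ValueError, match="folds"):
            TrainingConfig(folds=1)


class TestConnectivityMeasures:
    def test_quadratic_coupling_raises_nc_in_the_right_direction(self):
        coeffs = np.zeros((2, 2, 1))
        coeffs[0, 0, 0], coeffs[1, 1, 0] = 0.5, 0.4
        ep = simulate_nmvar(CoupledSystemSpec(
            n_channels=2, order=1, linear_coeffs=coeffs,
            nonlinear_terms=[NonlinearTerm(0, 1, 1, "quadratic", 0.5)],
            noise_sd=1.0, samples_per_trial=1000, seed=13))
        res = estimate_connectivity(ep, TrainingConfig(seed=13,
                                                       compute_cv=False), 1)
        assert res.nc[0, 1] > 0.2
        assert res.nc[0, 1] > res.nc[1, 0] + 0.1

    def test_nc_never_much_below_zero_on_fitted_data(self, var1_spec):
        ep = simulate_nmvar(var1_spec)
        res = estimate_connectivity(ep, TrainingConfig(seed=1,
                                                       compute_cv=False), 1)
        assert np.min(res.nc) >= -0.05

    def test_degenerate_perfect_fit_rejected(self):
        # the zero network predicts the all-zero series exactly: zero
        # residual makes the error ratio undefined
        model = _hand_model(np.zeros((1, 2)), np.zeros(1),
                            np.zeros((2, 1)), np.zeros(2))
        with pytest.raises(ValueError, match="degenerate"):
            nonlinear_connectivity(model, np.zeros((1, 2, 50)))

    def test_permutation_equivariance_of_both_measures(self, rng):
        m, p, h = 3, 2, 4
        W1 = rng.normal(size=(h, m * p))
        b1 = rng.normal(size=h)
        W2 = rng.normal(size=(m, h))
        b2 = rng.normal(size=m)
        data = rng.standard_normal((2, m, 200))
        model = NMVARModel(W_in=W1, b_hidden=b1, W_out=W2, b_out=b2,
                           order=p, activation="tanh",
                           channel_means=data.mean(axis=(0, 2)),
                           channel_sds=data.std(axis=(0, 2)),
                           channel_names=["a", "b", "c"])
        perm = np.array([2, 0, 1])
        W1p = np.empty_like(W1)
        for k in range(p):
            W1p[:, k * m:(k + 1) * m] = W1[:, k * m:(k + 1) * m][:, perm]
        modelp = NMVARModel(W_in=W1p, b_hidden=b1, W_out=W2[perm],
                            b_out=b2[perm], order=p, activation="tanh",
                            channel_means=model.channel_means[perm],
                            channel_sds=model.channel_sds[perm],
                            channel_names=["c", "a", "b"])
        datap = data[:, perm, :]
        lc, lcp = linear_connectivity(model), linear_connectivity(modelp)
        nc = nonlinear_connectivity(model, data)
        ncp = nonlinear_connectivity(modelp, datap)
        assert np.allclose(lcp, lc[np.ix_(perm, perm)])
        assert np.allclose(ncp, nc[np.ix_(perm, perm)])

    def test_model_serialization_round_trip(self, var1_spec):
        ep = simulate_nmvar(var1_spec)
        model, _ = fit_nmvar(ep, TrainingConfig(seed=1, compute_cv=False,
                                                max_epochs=20), 1)
        clone = NMVARModel.from_dict(model.to_dict())
        x = np.array([0.3, -0.7])
        assert np.allclose(clone.predict(x), model.predict(x))
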