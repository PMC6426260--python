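"""Response estimation: OLS/GLS/WLS, pooled REML noise models, Eq-style
hand-checked toys, and parameter recovery on simulated data."""

import numpy as np
import pytest

import fmrinc.glm as glm
from fmrinc.design import StimulusDesign
from fmrinc.glm import (
    NoiseCovarianceModel,
    TimeSeriesDataset,
    estimate_ar1_covariance,
    estimate_nonstationary_weights,
    fit_gls,
    fit_ols,
    run_to_run_variance,
)


def _design(matrix, runs=None, tr=1.0):
    matrix = np.asarray(matrix, dtype=float)
    runs = np.zeros(matrix.shape[0], int) if runs is None else np.asarray(runs)
    return StimulusDesign(matrix=matrix, run_index=runs, tr_seconds=tr)


def _data(signal, runs=None):
    signal = np.asarray(signal, dtype=float)
    runs = np.zeros(signal.shape[0], int) if runs is None else np.asarray(runs)
    return TimeSeriesDataset(signal=signal, run_index=runs)


class TestOLS:
    def test_three_point_toy(self):
        # single constant regressor on y = (1, 2, 3): mean 2, resid var 1
        est, noise = fit_ols(_data([1., 2., 3.]), _design([[1.], [1.], [1.]]),
                             fit_runs=False)
        assert est.beta_hat[0, 0] == pytest.approx(2.0)
        assert est.var_diag[0, 0] == pytest.approx(1.0 / 3.0)
        assert noise.kind == "identity"
        assert np.allclose(noise.omega(0), np.eye(3))

    def test_orthonormal_noiseless_recovers_beta_exactly(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).standard_normal((12, 4)))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        est, _ = fit_ols(_data(q @ beta), _design(q), fit_runs=False)
        assert np.allclose(est.beta_hat[:, 0], beta, atol=1e-12)
        assert np.all(est.var_diag < 1e-20)

    def test_rank_deficiency_names_dependent_columns(self):
        phi = np.ones((6, 2))  # duplicated column
        with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
            fit_ols(_data(np.arange(6.0)), _design(phi))

    def test_standardized_errors_have_unit_variance(self, small_dataset):
        # (beta_hat - beta) / sqrt(var_diag) should be ~N(0, 1)
        spec, design, truth, data = small_dataset
        est, _ = fit_ols(data, design, fit_runs=False)
        z = (est.beta_hat - truth.beta_common) / np.sqrt(est.var_diag)
        assert np.var(z) == pytest.approx(1.0, rel=0.10)


class TestGLS:
    def test_diagonal_toy_weighted_mean(self):
        model = NoiseCovarianceModel(
            kind="nonstationary", run_lengths={0: 4},
            hyperparameters={"weights": {0: np.array([1., 1., 4., 4.])}},
        )
        est = fit_gls(_data([0., 2., 4., 6.]), _design(np.ones((4, 1))),
                      model, fit_runs=False)
        assert est.beta_hat[0, 0] == pytest.approx(1.8)

    def test_identity_covariance_reproduces_ols(self, small_dataset):
        spec, design, truth, data = small_dataset
        est_ols, noise = fit_ols(data, design, fit_runs=False)
        est_gls = fit_gls(data, design, noise, fit_runs=False)
        assert np.allclose(est_gls.beta_hat, est_ols.beta_hat, rtol=1e-10)
        assert np.allclose(est_gls.var_diag, est_ols.var_diag, rtol=1e-10)

    def test_gls_closed_form_on_small_instance(self):
        # whitened solve must equal the explicit GLS formula
        rng = np.random.default_rng(5)
        phi = rng.standard_normal((30, 3))
        y = rng.standard_normal((30, 2))
        model = NoiseCovarianceModel(
            kind="ar1", run_lengths={0: 30},
            hyperparameters={"h": np.array([1.3, 0.8]),
                             "ar_basis_coef": 0.2},
        )
        omega = model.omega(0)
        oi = np.linalg.inv(omega)
        expected = np.linalg.solve(phi.T @ oi @ phi, phi.T @ oi @ y)
        est = fit_gls(_data(y), _design(phi), model, fit_runs=False)
        assert np.allclose(est.beta_hat, expected, rtol=1e-10)

    def test_variance_matches_sandwich_when_omega_is_true(self):
        # Vhat = (Phi' Om^-1 Phi)^-1 equals the sandwich form at Om_hat = Om
        rng = np.random.default_rng(6)
        phi = rng.standard_normal((40, 3))
        model = NoiseCovarianceModel(
            kind="ar1", run_lengths={0: 40},
            hyperparameters={"h": np.array([1.0, 0.5]),
                             "ar_basis_coef": 0.2},
        )
        omega = model.omega(0)
        oi = np.linalg.inv(omega)
        a = np.linalg.inv(phi.T @ oi @ phi)
        sandwich = a @ (phi.T @ oi @ omega @ oi @ phi) @ a
        assert np.allclose(np.diag(sandwich), np.diag(a), rtol=1e-10)

    def test_gls_more_efficient_than_ols_under_ar_noise(self):
        import fmrinc

        spec = fmrinc.ScenarioSpec(
            scenario="ar1", ar_coefficient=0.5, snr=1.0, n_voxels=300,
            n_stimuli_train=32, n_stimuli_test=16, n_features=16,
            n_replications=1, seed=42,
        )
        from fmrinc.simulate import _simulate_dataset, make_event_design

        dseed, rseed = np.random.SeedSequence(spec.seed).spawn(2)
        design = make_event_design(spec.n_stimuli, spec.n_runs,
                                   spec.tr_seconds, seed=dseed)
        truth, data, _ = _simulate_dataset(spec, design,
                                           np.random.default_rng(rseed))
        est_ols, _ = fit_ols(data, design, fit_runs=False)
        model = estimate_ar1_covariance(data, design)
        est_gls = fit_gls(data, design, model, fit_runs=False)
        # Gauss-Markov: true squared error of GLS below OLS on average
        err_ols = np.mean((est_ols.beta_hat - truth.beta_common) ** 2)
        err_gls = np.mean((est_gls.beta_hat - truth.beta_common) ** 2)
        assert err_gls < err_ols


class TestARCovariance:
    def test_white_noise_implies_near_zero_lag1(self, small_dataset):
        spec, design, truth, data = small_dataset
        model = estimate_ar1_covariance(data, design)
        assert abs(model.implied_lag1()) < 0.03

    def test_recovery_at_the_basis_coefficient(self):
        import fmrinc

        spec = fmrinc.ScenarioSpec(
            scenario="ar1", ar_coefficient=0.2, snr=1.0, n_voxels=1000,
            n_stimuli_train=48, n_stimuli_test=24, n_features=32,
            n_replications=1, seed=77,
        )
        from fmrinc.simulate import _simulate_dataset, make_event_design

        dseed, rseed = np.random.SeedSequence(spec.seed).spawn(2)
        design = make_event_design(spec.n_stimuli, spec.n_runs,
                                   spec.tr_seconds, seed=dseed)
        _, data, _ = _simulate_dataset(spec, design,
                                       np.random.default_rng(rseed))
        model = estimate_ar1_covariance(data, design)
        assert model.implied_lag1() == pytest.approx(0.2, abs=0.05)

        # stronger autocorrelation is detected but compressed by the fixed
        # 0.2-decay basis: partial recovery, monotone in the true lag-1
        spec2 = fmrinc.ScenarioSpec(
            scenario="ar1", ar_coefficient=0.4, snr=1.0, n_voxels=1000,
            n_stimuli_train=48, n_stimuli_test=24, n_features=32,
            n_replications=1, seed=78,
        )
        _, data2, _ = _simulate_dataset(spec2, design,
                                        np.random.default_rng(rseed))
        lag2 = estimate_ar1_covariance(data2, design).implied_lag1()
        assert 0.25 < lag2 <= 0.4 + 0.05
        assert lag2 > model.implied_lag1()

    def test_reconstructed_omega_is_spd(self):
        model = NoiseCovarianceModel(
            kind="ar1", run_lengths={0: 50},
            hyperparameters={"h": np.array([1.0, 0.6]),
                             "ar_basis_coef": 0.2},
        )
        omega = model.omega(0)
        assert np.allclose(omega, omega.T)
        assert np.linalg.eigvalsh(omega).min() > 0
        w = model.whitener(0)
        assert np.allclose(w @ omega @ w.T, np.eye(50), atol=1e-10)

    def test_reml_scale_equivariance(self, small_dataset):
        spec, design, truth, data = small_dataset
        m1 = estimate_ar1_covariance(data, design)
        scaled = TimeSeriesDataset(signal=3.0 * data.signal,
                                   run_index=data.run_index)
        m2 = estimate_ar1_covariance(scaled, design)
        assert np.allclose(m2.hyperparameters["h"],
                           9.0 * m1.hyperparameters["h"], rtol=1e-3)

    def test_pool_too_small_raises(self, small_dataset):
        spec, design, truth, data = small_dataset
        with pytest.raises(ValueError, match="at least 2 voxels"):
            estimate_ar1_covariance(data, design, voxel_pool=[0])


class TestNonstationaryWeights:
    def test_stationary_input_gives_uniform_weights(self):
        # the per-volume variance estimates pool over voxels, so the spread
        # under white noise shrinks with the pool: use a large one
        rng = np.random.default_rng(31)
        from fmrinc.design import make_event_design

        design = make_event_design(16, 2, tr_seconds=2.0, seed=8)
        data = _data(rng.standard_normal((design.n_timepoints, 800)),
                     design.run_index)
        model = estimate_nonstationary_weights(data, design)
        for run, w in model.hyperparameters["weights"].items():
            assert np.std(w) / np.mean(w) < 0.10

    def test_scaled_volumes_get_largest_weights(self, nst_recovery):
        rates = []
        for row in nst_recovery.extras["voxelwise"]:
            w = row["nst_weights"]
            scaled = row["scaled_volumes"]
            thr = np.quantile(w, 0.9)
            rates.append(np.mean(w[scaled] >= thr))
        assert np.mean(rates) >= 0.9

    def test_single_volume_run_raises(self):
        phi = np.ones((3, 1))
        runs = np.array([0, 1, 1])
        with pytest.raises(ValueError, match="single volume|degrees"):
            estimate_nonstationary_weights(
                _data(np.random.default_rng(0).standard_normal((3, 4)), runs),
                _design(phi, runs),
            )


class TestRunToRun:
    def test_two_run_hand_example(self):
        by_run = np.array([[[0.0]], [[2.0]]])  # stimulus value 0 then 2
        est = glm.ResponseEstimate(
            beta_hat=by_run.mean(axis=0), var_diag=np.zeros((1, 1)),
            estimator_kind="identity", beta_hat_by_run=by_run,
        )
        r2r = run_to_run_variance(est)
        assert r2r.var_diag[0, 0] == pytest.approx(1.0)
        assert r2r.estimator_kind == "r2r"
        assert r2r.beta_hat[0, 0] == pytest.approx(1.0)

    def test_identical_runs_give_zero_variance(self):
        by_run = np.tile(np.arange(4.0)[None, :, None], (3, 1, 1))
        est = glm.ResponseEstimate(
            beta_hat=by_run.mean(axis=0), var_diag=np.zeros((4, 1)),
            estimator_kind="identity", beta_hat_by_run=by_run,
        )
        assert np.allclose(run_to_run_variance(est).var_diag, 0.0)

    def test_requires_at_least_two_complete_runs(self):
        est = glm.ResponseEstimate(
            beta_hat=np.zeros((3, 1)), var_diag=np.zeros((3, 1)),
            estimator_kind="identity",
        )
        with pytest.raises(ValueError, match=">= 2 runs"):
            run_to_run_variance(est)
        by_run = np.zeros((2, 3, 1))
        by_run[1, 2, 0] = np.nan  # stimulus missing from run 2
        est2 = glm.ResponseEstimate(
            beta_hat=np.zeros((3, 1)), var_diag=np.zeros((3, 1)),
            estimator_kind="identity", beta_hat_by_run=by_run,
        )
        with pytest.raises(ValueError, match="every run"):
            run_to_run_variance(est2)

    def test_agrees_with_parametric_variance_on_iid_data(self, small_dataset):
        # run-to-run and parametric OLS variances estimate the same quantity
        spec, design, truth, data = small_dataset
        est, _ = fit_ols(data, design, fit_runs=True)
        r2r = run_to_run_variance(est)
        ratio = np.mean(r2r.var_diag) / np.mean(est.var_diag)
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_run_mean_equals_whole_series_on_noiseless_data(self):
        rng = np.random.default_rng(9)
        from fmrinc.design import make_event_design

        design = make_event_design(8, 3, tr_seconds=2.0, seed=4)
        beta = rng.standard_normal((8, 2))
        data = _data(design.matrix @ beta, design.run_index)
        est, _ = fit_ols(data, design, fit_runs=True)
        assert np.allclose(est.beta_hat, beta, atol=1e-8)
        assert np.allclose(est.beta_hat_by_run.mean(axis=0), est.beta_hat,
                           atol=1e-8)


class TestContainers:
    def test_dataset_validation(self):
        with pytest.raises(ValueError, match="non-finite"):
            TimeSeriesDataset(signal=np.array([1.0, np.nan]),
                              run_index=np.array([0, 0]))
        with pytest.raises(ValueError, match="non-decreasing"):
            TimeSeriesDataset(signal=np.zeros(3),
                              run_index=np.array([1, 0, 1]))

    def test_beta_var_is_recomputable_unbiased_variance(self):
        rng = np.random.default_rng(2)
        bh = rng.standard_normal((10, 3))
        est = glm.ResponseEstimate(beta_hat=bh, var_diag=np.zeros((10, 3)),
                                   estimator_kind="identity")
        assert np.allclose(est.beta_var, bh.var(axis=0, ddof=1))
        assert np.allclose(est.beta_bar, bh.mean(axis=0))
        with pytest.raises(ValueError, match="non-negative"):
            glm.ResponseEstimate(beta_hat=bh, var_diag=-np.ones((10, 3)),
                                 estimator_kind="identity")
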