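"""Single-stimulus response estimation from fMRI time series.

Estimates per-stimulus response amplitudes ``beta_hat`` and their estimation
variances under three noise models:

* **identity** -- i.i.d. noise, ordinary least squares (OLS);
* **ar1** -- temporally autocorrelated noise.  The noise covariance is
  modelled as a two-component mixture ``h1*I + h2*K`` where ``K`` is a fixed
  AR basis (lag-k entry ``0.2**k``, zero diagonal), with the mixing weights
  fitted by restricted maximum likelihood (REML) on a covariance matrix
  pooled over a set of voxels -- the classic two-pass whitening procedure;
* **nonstationary** -- a diagonal covariance with one variance hyperparameter
  per volume, fitted by Fisher-scoring REML on the pooled residual energy
  (robust weighted least squares).

A fourth, non-parametric variance estimate -- the variance of the across-run
mean of the per-run estimates -- is provided by :func:`run_to_run_variance`.

All solvers are vectorised over voxels: ``signal`` is a (time x voxels)
matrix and every estimate comes back with a trailing voxel axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .design import StimulusDesign

__all__ = [
    "TimeSeriesDataset",
    "NoiseCovarianceModel",
    "ResponseEstimate",
    "fit_ols",
    "fit_gls",
    "estimate_ar1_covariance",
    "estimate_nonstationary_weights",
    "run_to_run_variance",
]

#: lag-1 coefficient of the fixed AR covariance basis (SPM convention).
DEFAULT_AR_BASIS_COEF = 0.2
#: REML stopping rules.  The Fisher-scoring step is measured relative to the
#: largest hyperparameter: stop below REML_TOL; a step stalled below
#: REML_STALL_TOL counts as converged (the pooled sample covariance has a
#: Monte-Carlo noise floor); a step above REML_FAIL_TOL after REML_MAX_ITER
#: iterations raises a non-convergence error.
REML_TOL = 1e-6
REML_STALL_TOL = 1e-4
REML_FAIL_TOL = 1e-3
REML_MAX_ITER = 64


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------

@dataclass
class TimeSeriesDataset:
    """Voxel time series with run structure.

    ``signal`` is (T, n_voxels); ``run_index`` labels each volume with its
    run, in contiguous non-decreasing blocks.
    """

    signal: np.ndarray
    run_index: np.ndarray
    tr_seconds: float = 2.6

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim == 1:
            self.signal = self.signal[:, None]
        self.run_index = np.asarray(self.run_index)
        if self.signal.shape[0] != self.run_index.shape[0]:
            raise ValueError("signal rows and run_index length differ")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if np.any(np.diff(self.run_index) < 0):
            raise ValueError("run_index must be contiguous non-decreasing")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[1]

    @property
    def n_runs(self) -> int:
        return int(np.unique(self.run_index).size)

    @property
    def run_ids(self) -> np.ndarray:
        return np.unique(self.run_index)

    def run_signal(self, run) -> np.ndarray:
        return self.signal[self.run_index == run]


@dataclass
class NoiseCovarianceModel:
    """Parametrised estimate of the time-series noise covariance.

    The covariance is block-diagonal over runs (noise independent between
    runs).  ``hyperparameters`` holds the REML estimates: for ``ar1`` the two
    mixture weights ``h`` plus the AR basis coefficient; for
    ``nonstationary`` a per-run vector of per-volume variances.
    """

    kind: str  # identity | ar1 | nonstationary
    run_lengths: dict
    hyperparameters: dict = field(default_factory=dict)
    pooled: bool = True

    def omega(self, run) -> np.ndarray:
        """Reconstruct the run's covariance matrix (small instances only)."""
        t = self.run_lengths[run]
        if self.kind == "identity":
            return np.eye(t)
        if self.kind == "ar1":
            h1, h2 = self.hyperparameters["h"]
            return h1 * np.eye(t) + h2 * _ar_basis(t, self.ar_basis_coef)
        if self.kind == "nonstationary":
            return np.diag(self.hyperparameters["weights"][run])
        raise ValueError(f"unknown covariance kind {self.kind!r}")

    def whitener(self, run) -> np.ndarray | None:
        """Matrix W with W Omega W' = I, or None for the identity model."""
        if self.kind == "identity":
            return None
        t = self.run_lengths[run]
        if self.kind == "ar1":
            h1, h2 = self.hyperparameters["h"]
            w, u = _ar_basis_eig(t, self.ar_basis_coef)
            d = h1 + h2 * w
            if np.any(d <= 0):
                raise ValueError("reconstructed covariance is not positive definite")
            return (u / np.sqrt(d)).T
        if self.kind == "nonstationary":
            v = self.hyperparameters["weights"][run]
            return np.diag(1.0 / np.sqrt(v))
        raise ValueError(f"unknown covariance kind {self.kind!r}")

    @property
    def ar_basis_coef(self) -> float:
        return self.hyperparameters.get("ar_basis_coef", DEFAULT_AR_BASIS_COEF)

    def implied_lag1(self) -> float:
        """Lag-1 autocorrelation of the fitted covariance (ar1 kind)."""
        if self.kind == "identity":
            return 0.0
        if self.kind != "ar1":
            raise ValueError("implied_lag1 is defined for the ar1 kind")
        h1, h2 = self.hyperparameters["h"]
        return float(self.ar_basis_coef * h2 / h1)


@dataclass
class ResponseEstimate:
    """Estimated per-stimulus responses and their estimation variances.

    ``beta_hat`` is (n_stimuli, n_voxels); ``beta_hat_by_run`` is
    (n_runs, n_stimuli, n_voxels) when per-run fits were requested (NaN for
    stimuli absent from a run); ``var_diag`` is the diagonal of the
    beta_hat covariance estimate, per stimulus and voxel.
    """

    beta_hat: np.ndarray
    var_diag: np.ndarray
    estimator_kind: str
    beta_hat_by_run: np.ndarray | None = None
    run_ids: np.ndarray | None = None
    combine: str = "whole_series"  # or "run_mean"

    def __post_init__(self) -> None:
        self.beta_hat = np.atleast_2d(np.asarray(self.beta_hat, dtype=float))
        if self.beta_hat.shape[0] == 1 and self.beta_hat.shape[1] > 1:
            # accept 1-D per-stimulus vectors
            self.beta_hat = self.beta_hat.T
        self.var_diag = np.broadcast_to(
            np.asarray(self.var_diag, dtype=float).reshape(
                -1, 1) if np.asarray(self.var_diag).ndim == 1 else np.asarray(
                self.var_diag, dtype=float),
            self.beta_hat.shape,
        ).copy()
        if np.any(self.var_diag < 0):
            raise ValueError("var_diag must be non-negative")

    @property
    def n_stimuli(self) -> int:
        return self.beta_hat.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.beta_hat.shape[1]

    @property
    def n_runs(self) -> int:
        return 0 if self.beta_hat_by_run is None else self.beta_hat_by_run.shape[0]

    @property
    def beta_bar(self) -> np.ndarray:
        """Mean response across stimuli, one value per voxel."""
        return self.beta_hat.mean(axis=0)

    @property
    def beta_var(self) -> np.ndarray:
        """Unbiased sample variance of beta_hat across stimuli, per voxel."""
        return self.beta_hat.var(axis=0, ddof=1)

    def subset(self, stimuli) -> "ResponseEstimate":
        """Restrict to a subset of stimuli (e.g. the test set)."""
        stimuli = np.asarray(stimuli)
        by_run = None
        if self.beta_hat_by_run is not None:
            by_run = self.beta_hat_by_run[:, stimuli, :]
        return ResponseEstimate(
            beta_hat=self.beta_hat[stimuli],
            var_diag=self.var_diag[stimuli],
            estimator_kind=self.estimator_kind,
            beta_hat_by_run=by_run,
            run_ids=self.run_ids,
            combine=self.combine,
        )

    def run_mean(self) -> "ResponseEstimate":
        """Replace beta_hat by the across-run mean of the per-run estimates."""
        if self.beta_hat_by_run is None:
            raise ValueError("per-run estimates are not available")
        if np.any(np.isnan(self.beta_hat_by_run)):
            raise ValueError("some stimuli are missing from some runs")
        return replace(
            self,
            beta_hat=self.beta_hat_by_run.mean(axis=0),
            var_diag=self.var_diag.copy(),
            combine="run_mean",
        )


# --------------------------------------------------------------------------
# AR basis cache
# --------------------------------------------------------------------------

_AR_CACHE: dict = {}


def _ar_basis(t: int, coef: float) -> np.ndarray:
    """AR covariance basis: lag-k entry coef**k, zero on the diagonal."""
    k = scipy.linalg.toeplitz(coef ** np.arange(t))
    np.fill_diagonal(k, 0.0)
    return k


def _ar_basis_eig(t: int, coef: float):
    key = (t, round(coef, 12))
    if key not in _AR_CACHE:
        w, u = np.linalg.eigh(_ar_basis(t, coef))
        _AR_CACHE[key] = (w, u)
    return _AR_CACHE[key]


# --------------------------------------------------------------------------
# least-squares machinery
# --------------------------------------------------------------------------

def _check_rank(phi: np.ndarray, label: str = "design") -> None:
    q, r, piv = scipy.linalg.qr(phi, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(phi.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < phi.shape[1]:
        bad = sorted(int(c) for c in piv[rank:])
        raise np.linalg.LinAlgError(
            f"{label} is rank deficient: columns {bad} are linearly "
            f"dependent on the others"
        )


def _solve_ls(phi: np.ndarray, y: np.ndarray):
    """Least squares via economy QR; returns (beta, xtx_inv_diag, dof, resid)."""
    _check_rank(phi)
    q, r = scipy.linalg.qr(phi, mode="economic")
    beta = scipy.linalg.solve_triangular(r, q.T @ y)
    rinv = scipy.linalg.solve_triangular(r, np.eye(r.shape[0]))
    xtx_inv_diag = np.sum(rinv**2, axis=1)
    resid = y - phi @ beta
    dof = phi.shape[0] - phi.shape[1]
    return beta, xtx_inv_diag, dof, resid


def _per_run_fits(data, design, noise=None):
    """Per-run (whitened) OLS fits; NaN for stimuli absent from a run."""
    runs = design.run_ids
    n_stim, n_vox = design.n_stimuli, data.n_voxels
    by_run = np.full((runs.size, n_stim, n_vox), np.nan)
    for i, run in enumerate(runs):
        sl = design.run_slice(run)
        phi_r = design.matrix[sl]
        y_r = data.signal[sl]
        if noise is not None:
            w = noise.whitener(run)
            if w is not None:
                phi_r = w @ phi_r
                y_r = w @ y_r
        present = np.flatnonzero(np.linalg.norm(phi_r, axis=0) > 0)
        beta_r, _, _, _ = _solve_ls(phi_r[:, present], y_r)
        by_run[i, present, :] = beta_r
    return by_run, runs


def fit_gls(
    data: TimeSeriesDataset,
    design: StimulusDesign,
    noise: NoiseCovarianceModel,
    fit_runs: bool = True,
) -> ResponseEstimate:
    """Generalised least squares under an estimated noise covariance.

    Solves ``beta_hat = (Phi' Om^-1 Phi)^-1 Phi' Om^-1 y`` by whitening each
    run with ``W`` (``W Om W' = I``) and running OLS on the whitened model;
    the variance estimate is ``sigma2 * diag((Phi' Om^-1 Phi)^-1)`` with
    ``sigma2`` the per-voxel whitened residual variance on ``T - p`` degrees
    of freedom (the trace of the whitened residual-forming matrix).
    """
    if data.signal.shape[0] != design.n_timepoints:
        raise ValueError("time dimension of data and design differ")
    blocks_phi, blocks_y = [], []
    for run in design.run_ids:
        sl = design.run_slice(run)
        w = noise.whitener(run)
        phi_r, y_r = design.matrix[sl], data.signal[sl]
        if w is not None:
            phi_r, y_r = w @ phi_r, w @ y_r
        blocks_phi.append(phi_r)
        blocks_y.append(y_r)
    phi_w = np.vstack(blocks_phi)
    y_w = np.vstack(blocks_y)
    beta, xtx_inv_diag, dof, resid = _solve_ls(phi_w, y_w)
    if dof <= 0:
        raise ValueError("no residual degrees of freedom (T <= n_stimuli)")
    sigma2 = np.sum(resid**2, axis=0) / dof
    var_diag = np.outer(xtx_inv_diag, sigma2)
    by_run = run_ids = None
    if fit_runs:
        by_run, run_ids = _per_run_fits(data, design, noise)
    return ResponseEstimate(
        beta_hat=beta,
        var_diag=var_diag,
        estimator_kind=noise.kind,
        beta_hat_by_run=by_run,
        run_ids=run_ids,
    )


def fit_ols(data: TimeSeriesDataset, design: StimulusDesign, fit_runs: bool = True):
    """Ordinary least squares (i.i.d. noise assumption).

    Returns the response estimate together with the identity noise model it
    implies, so the result can flow into the same downstream machinery as the
    GLS fits.
    """
    run_lengths = {
        run: int(np.sum(design.run_index == run)) for run in design.run_ids
    }
    noise = NoiseCovarianceModel(kind="identity", run_lengths=run_lengths)
    est = fit_gls(data, design, noise, fit_runs=fit_runs)
    return est, noise


def run_to_run_variance(est: ResponseEstimate) -> ResponseEstimate:
    """Non-parametric variance of the across-run mean of beta_hat.

    For stimulus i: ``sum_r (b_ir - mean_r b_ir)^2 / ((n_r - 1) n_r)``, i.e.
    the unbiased per-run variance divided by the number of runs.  The
    returned estimate uses the across-run mean as ``beta_hat`` and is tagged
    ``r2r``.
    """
    if est.beta_hat_by_run is None or est.beta_hat_by_run.shape[0] < 2:
        raise ValueError("run-to-run variance needs per-run estimates of >= 2 runs")
    if np.any(np.isnan(est.beta_hat_by_run)):
        raise ValueError("every stimulus must be estimated in every run")
    by_run = est.beta_hat_by_run
    n_r = by_run.shape[0]
    var = by_run.var(axis=0, ddof=1) / n_r
    return ResponseEstimate(
        beta_hat=by_run.mean(axis=0),
        var_diag=var,
        estimator_kind="r2r",
        beta_hat_by_run=by_run,
        run_ids=est.run_ids,
        combine="run_mean",
    )


# --------------------------------------------------------------------------
# pooled REML noise-covariance estimation
# --------------------------------------------------------------------------

def _pooled_residual_cov(data, design, voxel_pool):
    """Per-run OLS residual covariance pooled over the voxel pool."""
    if voxel_pool is None:
        voxel_pool = np.arange(data.n_voxels)
    voxel_pool = np.asarray(voxel_pool)
    if voxel_pool.size < 2:
        raise ValueError("voxel pool must contain at least 2 voxels")
    out = {}
    for run in design.run_ids:
        sl = design.run_slice(run)
        phi_r = design.matrix[sl]
        y_r = data.signal[sl][:, voxel_pool]
        beta_r, _, _, resid = _solve_ls(phi_r, y_r)
        out[run] = (resid @ resid.T) / voxel_pool.size, phi_r
    return out, voxel_pool.size


def estimate_ar1_covariance(
    data: TimeSeriesDataset,
    design: StimulusDesign,
    voxel_pool=None,
    ar_basis_coef: float = DEFAULT_AR_BASIS_COEF,
    tol: float = REML_TOL,
    max_iter: int = REML_MAX_ITER,
) -> NoiseCovarianceModel:
    """Two-pass pooled AR(1) noise model.

    Pass 1: OLS residuals of the voxel pool, pooled into one covariance
    matrix per run.  Pass 2: Fisher-scoring REML fit of the two-component
    model ``h1*I + h2*K`` (``K`` the fixed AR basis with lag-1 coefficient
    ``ar_basis_coef``), with one shared ``(h1, h2)`` across runs and the
    run's design as the fixed-effects projection.
    """
    per_run, n_pool = _pooled_residual_cov(data, design, voxel_pool)
    runs = list(per_run)
    if min(s.shape[0] for s, _ in per_run.values()) < 3:
        raise ValueError("runs are too short for lag-1 structure")

    # move everything into the AR-basis eigenspace (diagonalises both comps)
    eig = {}
    for run, (s, phi_r) in per_run.items():
        t = s.shape[0]
        w, u = _ar_basis_eig(t, ar_basis_coef)
        eig[run] = (w, u.T @ s @ u, u.T @ phi_r)

    # moment-based init: h1 ~ mean variance, h2 from the lag-1 covariance
    mean_var = np.mean([np.mean(np.diag(s)) for s, _ in per_run.values()])
    lag1 = np.mean(
        [np.mean(np.diag(s, 1)) for s, _ in per_run.values()]
    )
    h = np.array([mean_var, max(lag1 / ar_basis_coef, 0.0)])
    trace = [h.copy()]
    converged = False
    for _ in range(max_iter):
        grad = np.zeros(2)
        fisher = np.zeros((2, 2))
        for run in runs:
            w, s_t, phi_t = eig[run]
            d = h[0] + h[1] * w
            comps = (np.ones_like(w), w)
            b = phi_t / d[:, None]
            g = phi_t.T @ b
            p = np.diag(1.0 / d) - b @ np.linalg.solve(g, b.T)
            m = p @ s_t
            psp_diag = np.sum(m * p, axis=1)
            p_diag = np.diag(p)
            q = p**2
            for k, ck in enumerate(comps):
                grad[k] += -0.5 * n_pool * (ck @ p_diag - ck @ psp_diag)
                for l, cl in enumerate(comps):
                    fisher[k, l] += 0.5 * n_pool * (ck @ q @ cl)
        dh = np.linalg.solve(fisher, grad)
        step = 1.0
        while step > 1e-6:
            h_new = h + step * dh
            ok = all(
                np.all(h_new[0] + h_new[1] * eig[run][0] > 0) for run in runs
            ) and h_new[0] > 0
            if ok:
                break
            step /= 2.0
        h = h + step * dh
        trace.append(h.copy())
        scale = max(np.max(np.abs(h)), 1e-300)
        delta = np.max(np.abs(step * dh))
        if delta < tol * scale:
            converged = True
            break
        if len(trace) > 2:  # stalled at the sampling-noise floor
            prev = np.max(np.abs(trace[-2] - trace[-3]))
            if delta < REML_STALL_TOL * scale and delta > 0.99 * prev:
                converged = True
                break
    if not converged and delta > REML_FAIL_TOL * scale:
        raise RuntimeError(
            "AR(1) REML did not converge within "
            f"{max_iter} iterations; hyperparameter trace: {trace}"
        )
    run_lengths = {run: per_run[run][0].shape[0] for run in runs}
    return NoiseCovarianceModel(
        kind="ar1",
        run_lengths=run_lengths,
        hyperparameters={
            "h": h,
            "ar_basis_coef": ar_basis_coef,
            "n_iter": len(trace) - 1,
            "n_pool": n_pool,
        },
    )


def estimate_nonstationary_weights(
    data: TimeSeriesDataset,
    design: StimulusDesign,
    voxel_pool=None,
    tol: float = REML_TOL,
    max_iter: int = REML_MAX_ITER,
) -> NoiseCovarianceModel:
    """Per-volume noise variances by Fisher-scoring (Newton-type) REML.

    The covariance of each run is modelled as ``diag(h_t)`` with one
    hyperparameter per volume, fitted to the pooled residual covariance of
    the voxel pool (robust-WLS convention).  Weights are floored at 1e-6 of
    the mean initial variance to keep the whitener bounded.
    """
    per_run, n_pool = _pooled_residual_cov(data, design, voxel_pool)
    weights = {}
    n_iters = {}
    for run, (s, phi_r) in per_run.items():
        t = s.shape[0]
        if t < 2:
            raise ValueError(f"run {run!r} has a single volume; cannot fit weights")
        if t <= phi_r.shape[1]:
            raise ValueError(
                f"run {run!r} has no residual degrees of freedom "
                f"({t} volumes, {phi_r.shape[1]} regressors)"
            )
        h = np.diag(s).copy()
        h = np.maximum(h, 1e-12)
        floor = 1e-6 * float(np.mean(h))
        trace_norm = []
        converged = False
        for it in range(max_iter):
            b = phi_r / h[:, None]
            g = phi_r.T @ b
            p = np.diag(1.0 / h) - b @ np.linalg.solve(g, b.T)
            psp_diag = np.sum((p @ s) * p, axis=1)
            grad = -0.5 * n_pool * (np.diag(p) - psp_diag)
            fisher = 0.5 * n_pool * p**2
            fisher[np.diag_indices(t)] += 1e-10 * np.max(np.abs(fisher))
            dh = np.linalg.solve(fisher, grad)
            step = 1.0
            while step > 1e-6 and np.any(h + step * dh <= 0):
                step /= 2.0
            h = np.maximum(h + step * dh, floor)
            delta = np.max(np.abs(step * dh))
            trace_norm.append(float(delta))
            scale = max(float(np.max(np.abs(h))), 1e-300)
            stalled = (
                len(trace_norm) > 2
                and delta < REML_STALL_TOL * scale
                and delta > 0.99 * trace_norm[-2]
            )
            if delta < tol * scale or stalled:
                converged = True
                n_iters[run] = it + 1
                break
        if not converged and delta > REML_FAIL_TOL * scale:
            raise RuntimeError(
                f"non-stationary REML did not converge for run {run!r} in "
                f"{max_iter} iterations; step-size trace: {trace_norm}"
            )
        n_iters.setdefault(run, max_iter)
        weights[run] = h
    run_lengths = {run: per_run[run][0].shape[0] for run in per_run}
    return NoiseCovarianceModel(
        kind="nonstationary",
        run_lengths=run_lengths,
        hyperparameters={
            "weights": weights,
            "n_iter": n_iters,
            "n_pool": n_pool,
            "floor": "1e-6 * mean initial variance",
        },
    )
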