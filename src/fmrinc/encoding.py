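"""Linearised encoding models: ridge regression and prediction metrics.

The encoding model assumes the response vector is a linear function of a
stimulus feature matrix ``X`` through a population receptive field (pRF)
weight vector: ``beta = X @ P``.  The pRF is estimated from training
responses by ridge regression and evaluated on held-out test responses with
the sample correlation ``rho``, the predictive ``R^2`` (which is unbounded
below on test data), the predictive squared Euclidean distance ``D^2`` and
the variance ratio ``gamma`` that links the two metrics.

Everything is vectorised over voxels: response arguments may be
(n_stimuli,) vectors or (n_stimuli, n_voxels) matrices, and scoring a matrix
columnwise is identical to scoring each voxel separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "EncodingFit",
    "PredictionMetrics",
    "fit_ridge",
    "predict",
    "score",
    "r2_identity_check",
]


def _as_columns(beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    return beta[:, None] if beta.ndim == 1 else beta


@dataclass
class EncodingFit:
    """Ridge regression fit of the population receptive field.

    ``prf_hat`` is (n_features, n_voxels); ``centering`` records the training
    mean removed from each voxel's responses before the fit.
    """

    prf_hat: np.ndarray
    lam: float
    centering: np.ndarray
    feature_matrix_train: np.ndarray

    @property
    def n_features(self) -> int:
        return self.prf_hat.shape[0]


@dataclass
class PredictionMetrics:
    """Test-set agreement between predicted and estimated responses.

    Each field is one value per voxel.  Voxels whose observed test responses
    have zero variance get NaN metrics and are flagged in ``undefined``
    rather than raising.
    """

    rho: np.ndarray
    r2: np.ndarray
    d2: np.ndarray
    gamma: np.ndarray
    pred_mean_bias: np.ndarray
    obs_mean: np.ndarray
    obs_var: np.ndarray
    n_test: int
    undefined: np.ndarray


def fit_ridge(beta_hat_train, features_train, lam: float) -> EncodingFit:
    """Estimate the pRF: ``P_hat = (X'X + lam I)^-1 X' beta_centered``.

    The training responses are mean-centred over stimuli first (the removed
    mean is stored on the fit).  Solved through a Cholesky factorisation of
    the regularised normal equations; with ``lam = 0`` the features must
    have full column rank.
    """
    x = np.asarray(features_train, dtype=float)
    beta = _as_columns(beta_hat_train)
    if x.ndim != 2 or x.shape[0] != beta.shape[0]:
        raise ValueError("features_train rows must match training stimuli")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    centering = beta.mean(axis=0)
    beta_c = beta - centering
    gram = x.T @ x + lam * np.eye(x.shape[1])
    try:
        cho = scipy.linalg.cho_factor(gram)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "X'X + lam*I is singular; the feature matrix is rank deficient "
            "-- use lam > 0"
        ) from exc
    prf = scipy.linalg.cho_solve(cho, x.T @ beta_c)
    return EncodingFit(
        prf_hat=prf, lam=float(lam), centering=centering,
        feature_matrix_train=x,
    )


def predict(fit: EncodingFit, features_test) -> np.ndarray:
    """Predicted responses ``beta_star = X_test @ P_hat`` (no re-centring)."""
    x = np.asarray(features_test, dtype=float)
    if x.ndim != 2 or x.shape[1] != fit.n_features:
        raise ValueError(
            f"features_test must be (n_test, {fit.n_features})"
        )
    return x @ fit.prf_hat


def score(beta_hat_test, beta_star) -> PredictionMetrics:
    """Score predictions against estimated test responses.

    rho: sample correlation with unbiased (n-1) variances.
    r2:  1 - sum (b_i - b*_i)^2 / sum (b_i - mean b)^2.
    d2:  (n-1) * var(b) * (1 - r2), the predictive squared distance.
    gamma: sd(beta_star) / sd(beta_hat_test).
    """
    obs = _as_columns(beta_hat_test)
    pred = _as_columns(beta_star)
    if obs.shape != pred.shape:
        raise ValueError("beta_hat_test and beta_star shapes differ")
    n = obs.shape[0]
    if n < 3:
        raise ValueError("need at least 3 test stimuli")
    obs_mean = obs.mean(axis=0)
    pred_mean = pred.mean(axis=0)
    obs_var = obs.var(axis=0, ddof=1)
    pred_var = pred.var(axis=0, ddof=1)
    undefined = obs_var == 0

    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.sum((obs - obs_mean) * (pred - pred_mean), axis=0) / (n - 1)
        rho = cov / np.sqrt(obs_var * pred_var)
        ss_err = np.sum((obs - pred) ** 2, axis=0)
        ss_tot = (n - 1) * obs_var
        r2 = 1.0 - ss_err / ss_tot
        gamma = np.sqrt(pred_var / obs_var)
    rho = np.where(undefined | (pred_var == 0), np.nan, rho)
    r2 = np.where(undefined, np.nan, r2)
    gamma = np.where(undefined, np.nan, gamma)
    d2 = (n - 1) * obs_var * (1.0 - r2)

    squeeze = np.asarray(beta_hat_test).ndim == 1

    def _out(a):
        return float(a[0]) if squeeze else a

    return PredictionMetrics(
        rho=_out(rho), r2=_out(r2), d2=_out(d2), gamma=_out(gamma),
        pred_mean_bias=_out(pred_mean), obs_mean=_out(obs_mean),
        obs_var=_out(obs_var), n_test=n, undefined=_out(undefined),
    )


def r2_identity_check(metrics: PredictionMetrics) -> np.ndarray:
    """Residual of the R^2 / rho identity for zero-mean observed responses.

    For test responses centred to zero mean,
    ``r2 = 2 rho gamma - gamma^2 - n/(n-1) * pred_mean_bias^2 / obs_var``;
    returns the absolute residual of that identity (0 up to round-off when
    the centring precondition holds).
    """
    n = metrics.n_test
    rhs = (
        2.0 * metrics.rho * metrics.gamma
        - np.asarray(metrics.gamma) ** 2
        - (n / (n - 1.0))
        * np.asarray(metrics.pred_mean_bias) ** 2
        / np.asarray(metrics.obs_var)
    )
    return np.abs(metrics.r2 - rhs)
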