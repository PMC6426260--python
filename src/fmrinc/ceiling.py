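"""Test-data noise ceilings for voxelwise encoding models.

The noise ceiling is the expected prediction accuracy of the *true*
generating model on noisy test responses -- an upper bound imposed purely by
the measurement noise of the test data.  Three estimators are provided:

* **analytic** -- ``rho_nc = sqrt((var(beta_hat) - mean V_ii) / var(beta_hat))``
  where ``V_ii`` are the per-stimulus estimation variances;
* **monte_carlo** -- the same signal/noise variance split, but the ceiling is
  the median correlation between resampled noise-free signals and their
  noise-contaminated copies;
* **split_half** -- the correlation between responses estimated from two
  disjoint halves of the runs, corrected for halving the data by
  ``2 rho / (rho + 1)``.

A negative estimated signal variance (analytic / Monte Carlo) or a negative
split-half correlation maps the ceiling to 0 (the model can do no better
than chance), with the ``clipped`` flag set.  Ceilings are reported in
correlation units with the squared value as the R^2-domain counterpart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import ResponseEstimate

__all__ = [
    "NoiseCeilingEstimate",
    "analytic_nc",
    "monte_carlo_nc",
    "split_half_nc",
    "split_runs",
    "nc_to_r2",
    "noise_corrected_accuracy",
    "true_noise_ceiling",
]


@dataclass
class NoiseCeilingEstimate:
    """A noise-ceiling value per voxel, with method provenance.

    ``rho_nc`` is in correlation units, clipped to [0, 1]; ``r2_nc`` is the
    R^2-domain counterpart ``rho_nc ** 2``.  ``sigma_beta2`` and
    ``sigma_eps2`` are the estimated noise-free signal variance and the
    pooled estimation-noise variance (NaN where a method does not use them).
    """

    rho_nc: np.ndarray
    method: str  # analytic | monte_carlo | split_half
    variance_source: str  # identity | ar1 | nonstationary | r2r | none
    sigma_beta2: np.ndarray
    sigma_eps2: np.ndarray
    clipped: np.ndarray
    undefined: np.ndarray
    extra: dict | None = None

    @property
    def r2_nc(self) -> np.ndarray:
        return np.asarray(self.rho_nc) ** 2


def _squeeze_like(value, template):
    arr = np.asarray(value)
    return float(arr[0]) if np.ndim(template) == 0 and arr.size == 1 else arr


def _variance_split(est: ResponseEstimate):
    if est.n_stimuli < 3:
        raise ValueError("need at least 3 stimuli for a noise ceiling")
    beta_var = est.beta_var
    eps2 = est.var_diag.mean(axis=0)
    return beta_var, eps2


def analytic_nc(est: ResponseEstimate) -> NoiseCeilingEstimate:
    """Analytical noise ceiling from the variance split.

    ``rho_nc = sqrt((sigma_bhat^2 - mean_i V_ii) / sigma_bhat^2)``; set to 0
    (clipped) when the mean estimation variance exceeds the response
    variance, and NaN (undefined) for voxels with zero response variance.
    """
    beta_var, eps2 = _variance_split(est)
    undefined = beta_var == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        radicand = (beta_var - eps2) / beta_var
    clipped = (radicand < 0) & ~undefined
    rho = np.sqrt(np.clip(radicand, 0.0, None))
    rho = np.where(undefined, np.nan, rho)
    return NoiseCeilingEstimate(
        rho_nc=rho,
        method="analytic",
        variance_source=est.estimator_kind,
        sigma_beta2=np.maximum(beta_var - eps2, 0.0),
        sigma_eps2=eps2,
        clipped=clipped,
        undefined=undefined,
    )


def monte_carlo_nc(
    est: ResponseEstimate,
    n_samples: int = 1000,
    seed=None,
    chunk: int = 128,
) -> NoiseCeilingEstimate:
    """Monte Carlo noise ceiling.

    Per voxel: estimate the noise-free signal variance as
    ``max(var(beta_hat) - mean V_ii, 0)``, draw ``n_samples`` noise-free
    signals from ``N(mean(beta_hat), sigma_beta^2)`` of length n_stimuli, add
    noise ``N(0, mean V_ii)`` and report the median of the signal/measurement
    correlations.  Deterministic given ``seed``.
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    beta_var, eps2 = _variance_split(est)
    beta_var = np.atleast_1d(beta_var)
    eps2 = np.atleast_1d(eps2)
    undefined = beta_var == 0
    sig2 = np.maximum(beta_var - eps2, 0.0)
    clipped = ((beta_var - eps2) < 0) & ~undefined
    n = est.n_stimuli
    rng = np.random.default_rng(seed)
    med = np.empty(beta_var.shape)
    for start in range(0, beta_var.size, chunk):
        sl = slice(start, min(start + chunk, beta_var.size))
        nv = sl.stop - sl.start
        signal = rng.standard_normal((n_samples, n, nv)) * np.sqrt(sig2[sl])
        noise = rng.standard_normal((n_samples, n, nv)) * np.sqrt(eps2[sl])
        meas = signal + noise
        sc = signal - signal.mean(axis=1, keepdims=True)
        mc = meas - meas.mean(axis=1, keepdims=True)
        num = np.sum(sc * mc, axis=1)
        den = np.sqrt(np.sum(sc**2, axis=1) * np.sum(mc**2, axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        r = np.where(den == 0, 1.0 if np.all(eps2[sl] == 0) else np.nan, r)
        # a zero-variance noise-free draw only happens when sig2 == 0: the
        # correlation is then defined to be 0 (chance level)
        r = np.nan_to_num(r, nan=0.0)
        med[sl] = np.median(r, axis=0)
    med = np.where(sig2 == 0, 0.0, med)
    med = np.where(eps2 == 0, 1.0, med)
    med = np.where(undefined, np.nan, np.clip(med, 0.0, 1.0))
    return NoiseCeilingEstimate(
        rho_nc=_squeeze_like(med, est.beta_var),
        method="monte_carlo",
        variance_source=est.estimator_kind,
        sigma_beta2=_squeeze_like(sig2, est.beta_var),
        sigma_eps2=_squeeze_like(eps2, est.beta_var),
        clipped=_squeeze_like(clipped, est.beta_var),
        undefined=_squeeze_like(undefined, est.beta_var),
        extra={"n_samples": n_samples, "seed": seed},
    )


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = np.sum(ac * bc, axis=0)
    den = np.sqrt(np.sum(ac**2, axis=0) * np.sum(bc**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den == 0, np.nan, num / den)


def split_half_nc(
    est_half1: ResponseEstimate, est_half2: ResponseEstimate
) -> NoiseCeilingEstimate:
    """Split-half noise ceiling with the half-to-full correction.

    ``rho = corr(beta_hat_1, beta_hat_2)`` over stimuli; the corrected
    reliability ``2 rho / (rho + 1)`` accounts for each half holding half
    the trials.  That corrected value is the ceiling in the R^2 domain
    (it equals the signal-variance fraction of the full-data estimate), so
    the correlation-domain ceiling is its square root:
    ``rho_nc = sqrt(2 rho / (rho + 1))`` for positive rho, and 0 (clipped)
    otherwise.  ``r2_nc`` recovers the corrected reliability itself.
    """
    if est_half1.n_stimuli != est_half2.n_stimuli:
        raise ValueError("both halves must estimate the same stimulus set")
    rho = _pearson_columns(
        np.atleast_2d(est_half1.beta_hat), np.atleast_2d(est_half2.beta_hat)
    )
    undefined = np.isnan(rho)
    clipped = (rho <= 0) & ~undefined
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = np.where(rho > 0, np.sqrt(2.0 * rho / (rho + 1.0)), 0.0)
    nc = np.where(undefined, np.nan, nc)
    nan = np.full(np.shape(nc), np.nan)
    return NoiseCeilingEstimate(
        rho_nc=_squeeze_like(nc, est_half1.beta_var),
        method="split_half",
        variance_source="none",
        sigma_beta2=_squeeze_like(nan, est_half1.beta_var),
        sigma_eps2=_squeeze_like(nan, est_half1.beta_var),
        clipped=_squeeze_like(clipped, est_half1.beta_var),
        undefined=_squeeze_like(undefined, est_half1.beta_var),
    )


def split_runs(est: ResponseEstimate, rule="odd_even"):
    """Split per-run estimates into two disjoint half-experiments.

    ``rule`` is ``"odd_even"`` (runs 1,3,5,... vs 2,4,6,...),
    ``"first_second"`` (first half of the runs vs second half) or an explicit
    pair of disjoint run-position lists.  Each half's ``beta_hat`` is the
    across-run mean of its runs.  With an odd run count the first half gets
    the extra run.
    """
    if est.beta_hat_by_run is None or est.beta_hat_by_run.shape[0] < 2:
        raise ValueError("splitting requires per-run estimates of >= 2 runs")
    if np.any(np.isnan(est.beta_hat_by_run)):
        raise ValueError("every stimulus must be estimated in every run")
    n_r = est.beta_hat_by_run.shape[0]
    if rule == "odd_even":
        half1 = list(range(0, n_r, 2))
        half2 = list(range(1, n_r, 2))
    elif rule == "first_second":
        cut = (n_r + 1) // 2
        half1 = list(range(0, cut))
        half2 = list(range(cut, n_r))
    else:
        half1, half2 = (list(map(int, h)) for h in rule)
        if set(half1) & set(half2):
            raise ValueError("explicit halves must be disjoint")
        if not half1 or not half2:
            raise ValueError("both halves must be non-empty")
        if not set(half1 + half2) <= set(range(n_r)):
            raise ValueError("run positions out of range")

    def _half(idx):
        sub = est.beta_hat_by_run[idx]
        return ResponseEstimate(
            beta_hat=sub.mean(axis=0),
            var_diag=np.zeros_like(est.var_diag),
            estimator_kind=est.estimator_kind,
            beta_hat_by_run=sub,
            combine="run_mean",
        )

    return _half(half1), _half(half2), (half1, half2)


def nc_to_r2(rho_nc) -> np.ndarray:
    """Map a correlation-domain ceiling to the R^2 domain.

    For the true model the predicted/observed variance ratio equals the
    ceiling itself and the mean bias vanishes, so the R^2 ceiling reduces to
    ``rho_nc ** 2``.
    """
    rho_nc = np.asarray(rho_nc, dtype=float)
    if np.any((rho_nc < 0) | (rho_nc > 1)):
        raise ValueError("rho_nc must lie in [0, 1]")
    out = rho_nc**2
    return float(out) if out.ndim == 0 else out


def noise_corrected_accuracy(rho_model, nc: NoiseCeilingEstimate):
    """Model accuracy divided by the noise ceiling.

    Reported alongside -- never instead of -- the raw accuracy; NaN where
    the ceiling is zero (the corrected value is undefined there).
    """
    rho_model = np.asarray(rho_model, dtype=float)
    ceiling = np.asarray(nc.rho_nc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(ceiling > 0, rho_model / ceiling, np.nan)
    return float(out) if out.ndim == 0 else out


def true_noise_ceiling(beta_true, beta_hat) -> np.ndarray:
    """Ground-truth ceiling: correlation between true and estimated responses.

    Only computable in simulations, where the noise-free responses are
    known.  The value depends on the estimator that produced ``beta_hat``
    (noisier estimators have lower true ceilings).  Voxels with zero
    variance in either vector come back NaN.
    """
    bt = np.asarray(beta_true, dtype=float)
    bh = np.asarray(beta_hat, dtype=float)
    if bt.ndim == 1:
        bt = bt[:, None]
    if bh.ndim == 1:
        bh = bh[:, None]
    if bt.shape[0] != bh.shape[0]:
        raise ValueError("beta_true and beta_hat lengths differ")
    if bt.shape[0] < 3:
        raise ValueError("need at least 3 stimuli")
    bt = np.broadcast_to(bt, bh.shape)
    r = _pearson_columns(bt, bh)
    return float(r[0]) if np.asarray(beta_hat).ndim == 1 else r
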