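"""Reproduction harnesses for the simulation experiments.

Each ``fig*`` function runs one of the validation experiments -- estimator
unbiasedness across noise levels, analytic vs Monte Carlo agreement,
estimator comparisons under each noise scenario, and the regularisation /
training-size study -- and returns tidy DataFrames (a per-condition summary
with means and [5, 95] percentiles, plus per-replication detail).

Sizes default to the full study conditions (126 + 42 stimuli, 128 features,
6 runs, 100 replications, 1000-voxel pools); ``scale`` shrinks replication
and voxel counts proportionally so a complete pass runs on one CPU in
minutes.  Stimulus/feature counts can be overridden explicitly for quick
property checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ceiling as nc
from .encoding import fit_ridge, predict, score
from .simulate import ScenarioSpec, run_scenario

__all__ = [
    "fig2_analytic_vs_truth",
    "fig3_mc_agreement",
    "fig4_iid_estimators",
    "fig5_autocorrelated",
    "fig6_nonstationary",
    "fig7_run_effects",
    "fig8_regularization",
    "FIGURES",
]

#: default noise-variance grid (signal variance is ~1, so SNR = 1/value)
NOISE_VAR_GRID = (0.25, 1.0, 4.0, 16.0)

_FULL_STUDY = dict(n_stimuli_train=126, n_stimuli_test=42, n_features=128,
                   n_runs=6)


def _sizes(scale, n_replications, n_voxels, overrides):
    reps = max(2, int(round(n_replications * scale)))
    vox = max(2, int(round(n_voxels * scale)))
    sz = dict(_FULL_STUDY)
    sz.update(overrides or {})
    return reps, vox, sz


def _scenario_sweep(
    scenario, grid, grid_field, seed, scale, n_replications, n_voxels,
    estimators, sizes, include_monte_carlo=False, extra_spec=None,
):
    reps, vox, sz = _sizes(scale, n_replications, n_voxels, sizes)
    rows, detail = [], []
    for i, value in enumerate(grid):
        kwargs = dict(scenario=scenario, n_replications=reps, n_voxels=vox,
                      seed=seed + 1000 * i, **sz, **(extra_spec or {}))
        kwargs[grid_field] = value
        spec = ScenarioSpec(**kwargs)
        res = run_scenario(spec, estimators=estimators,
                           include_monte_carlo=include_monte_carlo)
        s = res.summary()
        s.insert(0, grid_field, value)
        rows.append(s)
        t = res.table.copy()
        t.insert(0, grid_field, value)
        detail.append(t)
    return pd.concat(rows, ignore_index=True), pd.concat(detail, ignore_index=True)


def fig2_analytic_vs_truth(
    noise_vars=NOISE_VAR_GRID, seed=20, scale=1.0,
    n_replications=100, n_voxels=50, sizes=None,
):
    """Analytical ceiling (identity variance) vs ground truth, i.i.d. noise.

    One summary row per noise-variance level with the estimator and true
    means and [5, 95] bands, in the correlation domain; the R^2-domain
    ceiling is the squared value and is added as columns.
    """
    summary, detail = _scenario_sweep(
        "iid", [1.0 / v for v in noise_vars], "snr", seed, scale,
        n_replications, n_voxels, ("identity",), sizes,
    )
    summary["noise_var"] = 1.0 / summary["snr"]
    for col in ("nc_mean", "true_mean"):
        summary[col.replace("mean", "r2_mean")] = summary[col] ** 2
    detail["noise_var"] = 1.0 / detail["snr"]
    return summary, detail


def fig3_mc_agreement(
    noise_vars=NOISE_VAR_GRID, seed=30, scale=1.0, n_voxels=1000,
    mc_samples=1000, sizes=None,
):
    """Analytic vs Monte Carlo ceiling per voxel in the i.i.d. scenario.

    One replication of ``n_voxels`` voxels per noise level; returns the
    per-voxel pairs and agreement statistics (mean absolute difference and
    Spearman rank correlation across all voxels and levels).
    """
    from scipy.stats import spearmanr

    _, vox, sz = _sizes(scale, 1, n_voxels, sizes)
    pairs = []
    for i, noise_var in enumerate(noise_vars):
        spec = ScenarioSpec(scenario="iid", snr=1.0 / noise_var,
                            n_replications=1, n_voxels=vox,
                            seed=seed + 1000 * i, **sz)
        res = run_scenario(spec, estimators=("identity",),
                           include_monte_carlo=True, mc_samples=mc_samples,
                           collect_voxelwise=True)
        row = res.extras["voxelwise"][0]
        pairs.append(pd.DataFrame({
            "noise_var": noise_var,
            "analytic": row["identity"],
            "monte_carlo": row["monte_carlo"],
        }))
    detail = pd.concat(pairs, ignore_index=True)
    stats = pd.DataFrame([{
        "mean_abs_diff": float(
            np.mean(np.abs(detail["analytic"] - detail["monte_carlo"]))),
        "rank_correlation": float(
            spearmanr(detail["analytic"], detail["monte_carlo"]).statistic),
        "n_voxels": len(detail),
    }])
    return stats, detail


def fig4_iid_estimators(
    noise_vars=NOISE_VAR_GRID, seed=40, scale=1.0,
    n_replications=100, n_voxels=1000, sizes=None,
):
    """All five estimators across noise levels in the i.i.d. scenario."""
    summary, detail = _scenario_sweep(
        "iid", [1.0 / v for v in noise_vars], "snr", seed, scale,
        n_replications, n_voxels,
        ("identity", "ar1", "nonstationary", "r2r", "split_half"),
        sizes,
    )
    summary["noise_var"] = 1.0 / summary["snr"]
    return summary, detail


def fig5_autocorrelated(
    ar_grid=(0.2, 0.4, 0.6), seed=50, scale=1.0,
    n_replications=100, n_voxels=1000, sizes=None,
):
    """Estimator bias pattern as a function of the noise lag-1 autocorrelation."""
    return _scenario_sweep(
        "ar1", ar_grid, "ar_coefficient", seed, scale,
        n_replications, n_voxels,
        ("identity", "ar1", "nonstationary", "r2r", "split_half"), sizes,
    )


def fig6_nonstationary(
    factor_grid=(1.0, 2.0, 3.0), seed=60, scale=1.0,
    n_replications=100, n_voxels=1000, sizes=None, factor_random=False,
):
    """Estimator behaviour as the non-stationarity factor grows (SNR = 1)."""
    return _scenario_sweep(
        "nonstationary", factor_grid, "nst_factor", seed, scale,
        n_replications, n_voxels,
        ("identity", "ar1", "nonstationary", "r2r", "split_half"), sizes,
        extra_spec={"nst_factor_random": factor_random},
    )


def fig7_run_effects(
    noise_vars=(0.25, 1.0, 4.0), seed=70, scale=1.0,
    n_replications=100, n_voxels=1000, sizes=None,
    ar_coefficient=0.25, target_split_half=0.6,
):
    """Run-to-run response variability plus AR(0.25) noise."""
    summary, detail = _scenario_sweep(
        "ar1_run_effects", [1.0 / v for v in noise_vars], "snr", seed, scale,
        n_replications, n_voxels,
        ("identity", "ar1", "nonstationary", "r2r", "split_half"), sizes,
        extra_spec={"ar_coefficient": ar_coefficient,
                    "target_split_half": target_split_half},
    )
    summary["noise_var"] = 1.0 / summary["snr"]
    return summary, detail


#: default regularisation grid (lambda is treated as an experimental factor)
LAMBDA_GRID = tuple(np.logspace(-2, 4, 13))


def fig8_regularization(
    n_train_grid=(126, 252, 504, 756, 1008, 1260),
    lam_grid=(1.0, 1000.0),
    n_test=42,
    n_features=128,
    noise_var=0.5,
    n_replications=100,
    seed=80,
    scale=1.0,
):
    """True-model ridge performance vs the noise ceiling.

    Response-level experiment: true responses ``beta = X P`` with unit
    signal variance, observed responses ``beta + N(0, noise_var)``.  The
    true model's ridge fit is scored on the test responses and compared to
    the analytical ceiling computed with the generative noise variance as
    the per-stimulus estimation variance.  Returns mean model correlation
    and ceiling per (n_train, lambda) condition.
    """
    reps = max(2, int(round(n_replications * scale)))
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(reps):
        for n_tr in n_train_grid:
            x_tr = rng.standard_normal((n_tr, n_features)) / np.sqrt(n_features)
            x_te = rng.standard_normal((n_test, n_features)) / np.sqrt(n_features)
            p = rng.standard_normal(n_features)
            b_tr = x_tr @ p
            b_te = x_te @ p
            bh_tr = b_tr + rng.standard_normal(n_tr) * np.sqrt(noise_var)
            bh_te = b_te + rng.standard_normal(n_test) * np.sqrt(noise_var)
            est = _response_level_estimate(bh_te, noise_var)
            ceiling = float(np.atleast_1d(nc.analytic_nc(est).rho_nc)[0])
            for lam in lam_grid:
                fit = fit_ridge(bh_tr, x_tr, lam)
                pred = predict(fit, x_te)
                rho = score(bh_te, pred).rho
                rows.append({
                    "replication": rep, "n_train": n_tr, "lam": lam,
                    "rho_model": float(rho), "nc": ceiling,
                })
    detail = pd.DataFrame(rows)
    summary = (
        detail.groupby(["n_train", "lam"])
        .agg(rho_mean=("rho_model", "mean"),
             rho_p5=("rho_model", lambda g: np.percentile(g, 5)),
             rho_p95=("rho_model", lambda g: np.percentile(g, 95)),
             nc_mean=("nc", "mean"),
             nc_p5=("nc", lambda g: np.percentile(g, 5)),
             nc_p95=("nc", lambda g: np.percentile(g, 95)))
        .reset_index()
    )
    return summary, detail


def _response_level_estimate(beta_hat, noise_var):
    """Wrap a response vector as an estimate with a known noise variance."""
    from .glm import ResponseEstimate

    beta_hat = np.asarray(beta_hat, dtype=float)
    return ResponseEstimate(
        beta_hat=beta_hat,
        var_diag=np.full(beta_hat.shape[0], float(noise_var)),
        estimator_kind="identity",
    )


FIGURES = {
    "fig2": fig2_analytic_vs_truth,
    "fig3": fig3_mc_agreement,
    "fig4": fig4_iid_estimators,
    "fig5": fig5_autocorrelated,
    "fig6": fig6_nonstationary,
    "fig7": fig7_run_effects,
    "fig8": fig8_regularization,
}
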