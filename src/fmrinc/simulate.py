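"""Simulation engine: fMRI time series with known ground truth.

Generates voxel time series under four noise scenarios -- i.i.d. Gaussian,
AR(1)-autocorrelated, non-stationary (a random subset of volumes gets its
noise scaled up), and AR(1) noise combined with run-to-run response
variability -- runs the full estimation / noise-ceiling pipeline on each
replication, and compares every ceiling estimator against the ground-truth
ceiling, which is computable here because the noise-free responses are
known.

The default :class:`ScenarioSpec` mirrors the reference study conditions:
168 stimuli (126 training + 42 test) in a 128-feature space, 6 runs, 100
replications, and 1000 voxels sharing one noise covariance structure (the
ceiling is reported for the first voxel; the rest feed the pooled
covariance estimators).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.signal

from . import ceiling as nc
from . import glm
from .design import StimulusDesign, make_event_design

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "GroundTruth",
    "ScenarioResult",
    "gen_prf",
    "gen_features",
    "gen_noise",
    "gen_run_effects",
    "true_noise_ceiling",
    "run_scenario",
    "make_event_design",
]

SCENARIOS = ("iid", "ar1", "nonstationary", "ar1_run_effects")
ALL_ESTIMATORS = ("identity", "ar1", "nonstationary", "r2r", "split_half")

# re-exported: the ground-truth ceiling lives with the other ceiling math
true_noise_ceiling = nc.true_noise_ceiling


@dataclass
class ScenarioSpec:
    """Complete description of one simulation experiment.

    ``snr`` is the ratio of the noiseless signal variance (of the convolved
    time series, per voxel) to the noise variance; in the run-effects
    scenario only the run-common response term counts as signal.
    """

    scenario: str = "iid"
    snr: float = 1.0
    ar_coefficient: float = 0.0
    nst_factor: float = 1.0
    nst_fraction: float = 0.05
    nst_factor_random: bool = True
    target_split_half: float = 0.6
    n_voxels: int = 1000
    n_runs: int = 6
    n_stimuli_train: int = 126
    n_stimuli_test: int = 42
    n_features: int = 128
    n_replications: int = 100
    tr_seconds: float = 2.6
    isi_jitter: tuple = (2, 3, 4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError(
                "ar_coefficient must lie in [0, 1) for a stationary process"
            )
        if self.nst_factor < 1.0:
            raise ValueError("nst_factor must be >= 1")
        if not 0.0 <= self.nst_fraction <= 1.0:
            raise ValueError("nst_fraction must lie in [0, 1]")
        if not 0.0 < self.target_split_half < 1.0:
            raise ValueError("target_split_half must lie strictly in (0, 1)")
        for name in ("n_voxels", "n_runs", "n_stimuli_train",
                     "n_stimuli_test", "n_features", "n_replications"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        self.isi_jitter = tuple(int(j) for j in self.isi_jitter)

    @property
    def n_stimuli(self) -> int:
        return self.n_stimuli_train + self.n_stimuli_test

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ScenarioSpec":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)


@dataclass
class GroundTruth:
    """Noise-free quantities underlying one replication.

    ``beta_common`` = feature_matrix @ prf_true, per voxel; with run effects
    enabled the per-run truth is ``beta_common + run_effects[r]`` exactly.
    """

    prf_true: np.ndarray  # (n_features, n_voxels)
    feature_matrix: np.ndarray  # (n_stimuli, n_features)
    beta_common: np.ndarray  # (n_stimuli, n_voxels)
    train_idx: np.ndarray
    test_idx: np.ndarray
    run_effects: np.ndarray | None = None  # (n_runs, n_stimuli, n_voxels)

    def beta_run(self, r: int) -> np.ndarray:
        if self.run_effects is None:
            return self.beta_common
        return self.beta_common + self.run_effects[r]


def gen_prf(n_features: int, seed=None, n_voxels: int = 1) -> np.ndarray:
    """Population receptive fields drawn i.i.d. standard normal.

    Returns (n_features,) for a single voxel, else (n_features, n_voxels).
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = rng.standard_normal((n_features, n_voxels))
    return p[:, 0] if n_voxels == 1 else p


def gen_features(n_stimuli: int, n_features: int, rng=None) -> np.ndarray:
    """Stimulus feature matrix with N(0, 1/f) entries.

    The 1/f column variance makes the response variance over stimuli ~1 for
    a standard-normal pRF, so the signal scale matches the unit-signal
    convention of the noise scenarios.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return rng.standard_normal((n_stimuli, n_features)) / np.sqrt(n_features)


def gen_noise(spec: ScenarioSpec, run_lengths, signal_variance, rng):
    """Noise matrix (time x voxels) for the requested scenario.

    The per-voxel noise variance is ``signal_variance / snr``; noise is
    generated independently per run.  AR(1) series are rescaled to their
    realised standard deviation so the requested SNR holds exactly per run
    and voxel.  Returns ``(noise, info)`` where ``info`` records the scaled
    volumes and factors of the non-stationary scenario.
    """
    signal_variance = np.atleast_1d(np.asarray(signal_variance, dtype=float))
    if np.any(signal_variance <= 0):
        raise ValueError("signal_variance must be positive")
    target_sd = np.sqrt(signal_variance / spec.snr)
    n_vox = target_sd.size
    lengths = list(run_lengths.values()) if isinstance(run_lengths, dict) \
        else list(run_lengths)
    total = int(np.sum(lengths))
    info: dict = {"scaled_volumes": None, "factors": None}

    use_ar = spec.scenario in ("ar1", "ar1_run_effects") and spec.ar_coefficient > 0
    blocks = []
    for t_r in lengths:
        if use_ar:
            a = spec.ar_coefficient
            burn = 100
            innov = rng.standard_normal((t_r + burn, n_vox))
            series = scipy.signal.lfilter([1.0], [1.0, -a], innov, axis=0)[burn:]
            sd = series.std(axis=0, ddof=0)
            block = series / sd * target_sd
        else:
            block = rng.standard_normal((t_r, n_vox)) * target_sd
        blocks.append(block)
    noise = np.vstack(blocks)

    if spec.scenario == "nonstationary" and spec.nst_fraction > 0:
        n_scaled = int(round(spec.nst_fraction * total))
        scaled = rng.choice(total, size=n_scaled, replace=False)
        if spec.nst_factor_random:
            factors = rng.uniform(1.0, spec.nst_factor, size=n_scaled)
        else:
            factors = np.full(n_scaled, float(spec.nst_factor))
        noise[scaled] *= factors[:, None]
        info["scaled_volumes"] = np.sort(scaled)
        order = np.argsort(scaled)
        info["factors"] = factors[order]
    return noise, info


def gen_run_effects(
    n_stimuli: int,
    n_runs: int,
    target_split_half: float = 0.6,
    seed=None,
    sigma_common2: float = 1.0,
    n_voxels: int = 1,
):
    """Per-run additive response deviations calibrated to a split-half target.

    The run-common response has variance ``sigma_common2``; the run-specific
    deviations are zero-mean Gaussian with variance ``sigma_run2`` chosen so
    that the expected correlation between the mean noiseless responses of the
    two half-experiments equals ``target_split_half``:

        rho = s_c / sqrt((s_c + s_r/n1) (s_c + s_r/n2))

    solved in closed form for balanced halves, by root search otherwise.
    Returns ``(run_effects, info)`` with the calibration recorded in
    ``info`` (variance, mixing proportion, method).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    info = calibrate_run_effects(n_runs, target_split_half, sigma_common2)
    eff = rng.standard_normal(
        (n_runs, n_stimuli, n_voxels)) * np.sqrt(info["sigma_run2"])
    if n_voxels == 1:
        eff = eff[:, :, 0]
    return eff, info


def calibrate_run_effects(
    n_runs: int, target_split_half: float, sigma_common2: float = 1.0
) -> dict:
    """Solve for the run-effect variance hitting a split-half target."""
    if not 0.0 < target_split_half < 1.0:
        raise ValueError("target_split_half must lie strictly in (0, 1)")
    if n_runs < 2:
        raise ValueError("run effects need at least 2 runs")
    n1 = (n_runs + 1) // 2
    n2 = n_runs - n1
    s_c = float(sigma_common2)
    if n1 == n2:
        sigma_run2 = n1 * s_c * (1.0 - target_split_half) / target_split_half
        method = "analytic"
    else:
        def f(s_r):
            return (
                s_c / np.sqrt((s_c + s_r / n1) * (s_c + s_r / n2))
                - target_split_half
            )
        hi = 1.0
        while f(hi) > 0:
            hi *= 2.0
        sigma_run2 = float(scipy.optimize.brentq(f, 0.0, hi))
        method = "search"
    return {
        "sigma_run2": sigma_run2,
        "sigma_common2": s_c,
        "proportion_common": s_c / (s_c + sigma_run2),
        "method": method,
        "target_split_half": target_split_half,
        "half_sizes": (n1, n2),
    }


@dataclass
class ScenarioResult:
    """Per-replication ceiling estimates plus summary statistics."""

    spec: ScenarioSpec
    table: pd.DataFrame  # one row per replication x estimator
    extras: dict = field(default_factory=dict)
    n_failed: int = 0

    def summary(self) -> pd.DataFrame:
        """Mean and [5, 95] percentiles per estimator, estimate vs truth."""
        def agg(g):
            return pd.Series({
                "nc_mean": g["nc_est"].mean(),
                "nc_p5": np.percentile(g["nc_est"], 5),
                "nc_p95": np.percentile(g["nc_est"], 95),
                "true_mean": g["nc_true"].mean(),
                "true_p5": np.percentile(g["nc_true"], 5),
                "true_p95": np.percentile(g["nc_true"], 95),
                "n": len(g),
            })
        return (
            self.table.groupby("estimator", sort=False)
            .apply(agg, include_groups=False)
            .reset_index()
        )


def _simulate_dataset(spec, design, sim_rng, calib=None):
    """One replication: ground truth + noisy time series."""
    n_stim, n_vox = spec.n_stimuli, spec.n_voxels
    x = gen_features(n_stim, spec.n_features, sim_rng)
    p = gen_prf(spec.n_features, sim_rng, n_voxels=n_vox)
    p = p.reshape(spec.n_features, n_vox)
    beta_common = x @ p
    run_effects = None
    if spec.scenario == "ar1_run_effects":
        sigma_run2 = calib["sigma_run2"]
        run_effects = sim_rng.standard_normal(
            (spec.n_runs, n_stim, n_vox)) * np.sqrt(sigma_run2)
    truth = GroundTruth(
        prf_true=p,
        feature_matrix=x,
        beta_common=beta_common,
        train_idx=np.arange(spec.n_stimuli_train),
        test_idx=np.arange(spec.n_stimuli_train, n_stim),
        run_effects=run_effects,
    )
    run_ids = design.run_ids
    signal_blocks = []
    common_blocks = []
    for r, run in enumerate(run_ids):
        phi_r = design.run_matrix(run)
        common_blocks.append(phi_r @ beta_common)
        signal_blocks.append(phi_r @ truth.beta_run(r))
    signal = np.vstack(signal_blocks)
    common_signal = np.vstack(common_blocks)
    # only the run-common term counts as signal for the SNR definition
    sig_var = common_signal.var(axis=0, ddof=0)
    run_lengths = [int(np.sum(design.run_index == run)) for run in run_ids]
    noise, noise_info = gen_noise(spec, run_lengths, sig_var, sim_rng)
    data = glm.TimeSeriesDataset(
        signal=signal + noise,
        run_index=design.run_index,
        tr_seconds=spec.tr_seconds,
    )
    return truth, data, noise_info


def _estimate_all(spec, design, data, estimators):
    """Fit every requested estimator; returns ({name: estimate}, {models})."""
    out = {}
    models = {}
    ols_est, identity_model = glm.fit_ols(data, design, fit_runs=True)
    models["identity"] = identity_model
    if "identity" in estimators:
        out["identity"] = ols_est
    if "ar1" in estimators:
        model = glm.estimate_ar1_covariance(data, design)
        models["ar1"] = model
        out["ar1"] = glm.fit_gls(data, design, model, fit_runs=False)
    if "nonstationary" in estimators:
        model = glm.estimate_nonstationary_weights(data, design)
        models["nonstationary"] = model
        out["nonstationary"] = glm.fit_gls(data, design, model, fit_runs=False)
    if "r2r" in estimators:
        out["r2r"] = glm.run_to_run_variance(ols_est)
    if "split_half" in estimators:
        out["split_half"] = ols_est  # halves built from its per-run fits
    return out, models


def run_scenario(
    spec: ScenarioSpec,
    estimators=ALL_ESTIMATORS,
    include_monte_carlo: bool = False,
    mc_samples: int = 1000,
    report_voxel: int = 0,
    collect_voxelwise: bool = False,
) -> ScenarioResult:
    """Run a full simulation scenario.

    For each replication: simulate time series, estimate responses under
    every requested noise-covariance assumption, compute the matching
    analytical (or split-half / Monte Carlo) ceiling on the test stimuli,
    and the matched ground-truth ceiling.  The per-replication table reports
    voxel ``report_voxel``; ``collect_voxelwise`` additionally stores the
    full voxel arrays per replication (used for estimator-agreement
    scatter analyses).

    Deterministic given ``spec.seed``: all randomness descends from it.
    """
    estimators = tuple(estimators)
    unknown = set(estimators) - set(ALL_ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    ss = np.random.SeedSequence(spec.seed)
    design_seed, *rep_seeds = ss.spawn(spec.n_replications + 1)
    design = make_event_design(
        spec.n_stimuli, spec.n_runs, spec.tr_seconds, spec.isi_jitter,
        seed=design_seed,
    )
    calib = None
    extras: dict = {}
    if spec.scenario == "ar1_run_effects":
        _, calib = gen_run_effects(
            spec.n_stimuli, spec.n_runs, spec.target_split_half,
            seed=np.random.default_rng(0),  # only the calibration constants
        )
        extras["run_effect_calibration"] = calib

    rows = []
    voxelwise = []
    n_failed = 0
    test_idx = np.arange(spec.n_stimuli_train, spec.n_stimuli)
    for rep, rep_seed in enumerate(rep_seeds):
        rng = np.random.default_rng(rep_seed)
        try:
            truth, data, noise_info = _simulate_dataset(spec, design, rng, calib)
            fits, models = _estimate_all(spec, design, data, estimators)
        except Exception:
            n_failed += 1
            logger.exception("replication %d failed", rep)
            continue
        beta_ref = truth.beta_common[test_idx]
        if truth.run_effects is not None:
            # noiseless half-experiment correlation (calibration check)
            n_r = spec.n_runs
            cut = (n_r + 1) // 2
            beta_runs = np.stack(
                [truth.beta_run(r) for r in range(n_r)])  # (r, stim, vox)
            m1 = beta_runs[:cut].mean(axis=0)[:, report_voxel]
            m2 = beta_runs[cut:].mean(axis=0)[:, report_voxel]
            extras.setdefault("noiseless_split_half", []).append(
                float(np.corrcoef(m1, m2)[0, 1]))
        vox_row = {"replication": rep}
        for name in estimators:
            est = fits[name]
            if name == "split_half":
                sub = est.subset(test_idx)
                half1, half2, _ = nc.split_runs(sub, rule="odd_even")
                estimate = nc.split_half_nc(half1, half2)
                bh = sub.run_mean().beta_hat  # matched estimate for truth
            else:
                sub = est.subset(test_idx)
                bh = sub.beta_hat  # for r2r this is the across-run mean
                estimate = nc.analytic_nc(sub)
            true_vals = nc.true_noise_ceiling(beta_ref, bh)
            rows.append({
                "replication": rep,
                "estimator": name,
                "method": estimate.method,
                "nc_est": float(np.atleast_1d(estimate.rho_nc)[report_voxel]),
                "nc_true": float(np.atleast_1d(true_vals)[report_voxel]),
                "clipped": bool(np.atleast_1d(estimate.clipped)[report_voxel]),
            })
            if collect_voxelwise:
                vox_row[name] = np.atleast_1d(estimate.rho_nc).copy()
                vox_row[name + "_true"] = np.atleast_1d(true_vals).copy()
        if include_monte_carlo:
            sub = fits.get("identity", None)
            if sub is None:
                sub, _ = glm.fit_ols(data, design, fit_runs=False)
            sub = sub.subset(test_idx)
            mc = nc.monte_carlo_nc(sub, n_samples=mc_samples, seed=rng)
            rows.append({
                "replication": rep,
                "estimator": "monte_carlo",
                "method": "monte_carlo",
                "nc_est": float(np.atleast_1d(mc.rho_nc)[report_voxel]),
                "nc_true": float(np.atleast_1d(
                    nc.true_noise_ceiling(beta_ref, sub.beta_hat)
                )[report_voxel]),
                "clipped": bool(np.atleast_1d(mc.clipped)[report_voxel]),
            })
            if collect_voxelwise:
                vox_row["monte_carlo"] = np.atleast_1d(mc.rho_nc).copy()
        if collect_voxelwise:
            if noise_info.get("scaled_volumes") is not None:
                vox_row["scaled_volumes"] = noise_info["scaled_volumes"]
            if "nonstationary" in models:
                w = models["nonstationary"].hyperparameters["weights"]
                vox_row["nst_weights"] = np.concatenate(
                    [w[run] for run in design.run_ids])
            if "ar1" in models:
                vox_row["ar1_implied_lag1"] = models["ar1"].implied_lag1()
            voxelwise.append(vox_row)
    table = pd.DataFrame(rows)
    extras["n_replications_done"] = spec.n_replications - n_failed
    if collect_voxelwise:
        extras["voxelwise"] = voxelwise
    return ScenarioResult(spec=spec, table=table, extras=extras,
                          n_failed=n_failed)
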