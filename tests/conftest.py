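"""Shared fixtures: reduced-size simulation runs reused across test modules.

The simulation harnesses default to the full study conditions; tests run
them at reduced stimulus/feature counts (48 train + 24 test stimuli, 32
features, 6 runs) so the whole suite fits in a few CPU-minutes.  Pool sizes
follow the property under test: 1000 voxels where the pooled covariance
estimators are on trial, 200 otherwise.
"""

import numpy as np
import pytest

import fmrinc
import fmrinc.figures as figures

#: reduced stimulus/feature counts used by all simulation-based tests
SIZES = dict(n_stimuli_train=48, n_stimuli_test=24, n_features=32, n_runs=6)
NOISE_GRID = (0.25, 1.0, 4.0, 16.0)


@pytest.fixture(scope="session")
def iid_sweep():
    """All five estimators, i.i.d. noise, 50 replications per noise level."""
    summary, detail = figures.fig4_iid_estimators(
        noise_vars=NOISE_GRID, scale=1.0, n_replications=50, n_voxels=200,
        sizes=SIZES, seed=40,
    )
    return summary, detail


@pytest.fixture(scope="session")
def ar_bias():
    """Estimator comparison under AR(1) noise with lag-1 = 0.6."""
    summary, detail = figures.fig5_autocorrelated(
        ar_grid=(0.6,), scale=1.0, n_replications=25, n_voxels=1000,
        sizes=SIZES, seed=50,
    )
    return summary, detail


@pytest.fixture(scope="session")
def nst_sweep():
    """Estimator comparison as the non-stationarity factor grows."""
    summary, detail = figures.fig6_nonstationary(
        factor_grid=(1.0, 2.0, 3.0), scale=1.0, n_replications=15,
        n_voxels=1000, sizes=SIZES, seed=60,
    )
    return summary, detail


@pytest.fixture(scope="session")
def nst_recovery():
    """Per-volume weight estimates vs the truly scaled volumes (factor 3)."""
    spec = fmrinc.ScenarioSpec(
        scenario="nonstationary", nst_factor=3.0, nst_factor_random=False,
        snr=1.0, n_voxels=1000, n_replications=5, seed=61, **SIZES,
    )
    res = fmrinc.run_scenario(
        spec, estimators=("nonstationary",), collect_voxelwise=True)
    return res


@pytest.fixture(scope="session")
def run_effects_scenario():
    """AR(0.25) noise plus run-to-run response variability (split-half 0.6)."""
    summary, detail = figures.fig7_run_effects(
        noise_vars=(1.0,), scale=1.0, n_replications=40, n_voxels=200,
        sizes=SIZES, seed=70,
    )
    return summary, detail


@pytest.fixture(scope="session")
def mc_agreement():
    """Analytic vs Monte Carlo ceilings, 1000 voxels per noise level."""
    stats, detail = figures.fig3_mc_agreement(
        noise_vars=NOISE_GRID, scale=1.0, n_voxels=1000, mc_samples=1000,
        sizes=SIZES, seed=30,
    )
    return stats, detail


@pytest.fixture(scope="session")
def regularization_study():
    """True-model ridge vs ceiling across training sizes and lambdas."""
    summary, detail = figures.fig8_regularization(n_replications=60, seed=80)
    lam_summary, lam_detail = figures.fig8_regularization(
        n_train_grid=(126,), lam_grid=figures.LAMBDA_GRID,
        n_replications=40, seed=81,
    )
    return {"size": (summary, detail), "lam": (lam_summary, lam_detail)}


def band_check(summary, estimator, inside=True):
    """Whether the estimator's mean lies inside its matched true [5, 95] band
    at every grid level of a scenario summary."""
    sub = summary[summary["estimator"] == estimator]
    ok = (sub["nc_mean"] >= sub["true_p5"]) & (sub["nc_mean"] <= sub["true_p95"])
    return bool(ok.all()) == inside


@pytest.fixture(scope="session")
def small_dataset():
    """One small simulated i.i.d. dataset with its design and ground truth."""
    spec = fmrinc.ScenarioSpec(
        scenario="iid", snr=1.0, n_voxels=50, n_replications=1, seed=123,
        **SIZES,
    )
    from fmrinc.simulate import _simulate_dataset, make_event_design

    ss = np.random.SeedSequence(spec.seed)
    dseed, rseed = ss.spawn(2)
    design = make_event_design(
        spec.n_stimuli, spec.n_runs, spec.tr_seconds, spec.isi_jitter,
        seed=dseed,
    )
    truth, data, _ = _simulate_dataset(
        spec, design, np.random.default_rng(rseed))
    return spec, design, truth, data
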