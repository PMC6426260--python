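# Methods

## The quantity being estimated

A voxel's responses to `n` test stimuli are estimated from its fMRI time
series as `β̂`, a noisy measurement of the true response vector `β`.  Any
encoding model's test-set correlation is bounded by the correlation that the
*true* responses achieve with the noisy estimates.  Under the two-level
generative model `β̂ ~ N(β, V_β̂)` with `β` independent of the estimation
error, that bound is

    ρ_NC = σ_β / σ_β̂ = sqrt(σ²_β / (σ²_β + σ²_ε)),

where `σ²_β̂` is the variance of `β̂` across stimuli, `σ²_ε` the pooled
per-stimulus estimation variance (`mean(V̂ᵢᵢ)`), and `σ²_β = σ²_β̂ − σ²_ε`.
This is the test-data noise ceiling: it depends only on the test data and
the response-estimation procedure, not on any candidate model.  It is the
single-voxel, single-subject bound; between-subject variability and
group-level ceilings are out of scope.

Because `σ²_β` is estimated by subtraction it can come out negative (e.g.
voxels with no stimulus-driven signal).  All estimators clip the ceiling to
0 in that case and set a `clipped` flag; the R²-domain ceiling is defined as
`ρ̂²_NC`, so clipping propagates.

## Estimators

**Analytic.**  `ρ̂_NC = sqrt((σ̂²_β̂ − mean(V̂ᵢᵢ)) / σ̂²_β̂)` with the
arithmetic mean over stimuli.  `V̂ᵢᵢ` comes from whichever variance model
produced `β̂` (below), making the analytic ceiling a family of estimators
indexed by the noise assumption.

**Monte Carlo.**  The same variance split, evaluated by simulation: draw a
noise-free signal of length `n` from `N(β̂̄, σ̂²_β)`, add noise
`N(0, σ̂²_ε)`, correlate, repeat (default 1000 samples, seeded) and take
the median.  It has the same expectation as the analytic form and exists in
the package as an independent cross-check; the validation suite shows mean
absolute agreement ~0.003 with rank correlation > 0.999.

**Split-half.**  Estimate `β̂` separately from two disjoint halves of the
runs (default: odd vs even run positions; first-vs-second and explicit
splits are available, and with an odd run count the first half takes the
extra run).  For positive half-correlation `ρ`, the corrected reliability
`2ρ/(ρ+1)` equals `σ²_β/(σ²_β + v/2)` where `v` is the half-data noise
variance — i.e. the signal-variance fraction of the *full-data* estimate,
which is the ceiling in the R² domain.  The correlation-domain ceiling is
therefore `sqrt(2ρ/(ρ+1))`.  The square root matters: without it the
split-half value is systematically the square of the other estimators, a
bias our simulations resolve unambiguously.  Negative `ρ` maps to 0 with
the `clipped` flag.  Halves are built from per-run estimate averages rather
than per-half GLM refits (the run-to-run machinery already provides per-run
estimates); both β̂-construction paths are exposed.

**Ground truth (simulations only).**  `corr(β̂, β)` over the test stimuli.
It is matched to the estimator: a noisier estimation procedure has a lower
true ceiling, so each estimator is compared to the truth computed from its
own `β̂`.

Noise-corrected accuracies (`ρ_model / ρ̂_NC`) are emitted alongside — never
instead of — the raw accuracies, and are undefined (NaN) where the ceiling
is 0.

## Variance models for the response estimates

Responses are estimated per voxel by whitened least squares,
`β̂ = (ΦᵀΩ̂⁻¹Φ)⁻¹ΦᵀΩ̂⁻¹y`, with `V̂ = σ̂² diag((ΦᵀΩ̂⁻¹Φ)⁻¹)` and `σ̂²` the
per-voxel whitened residual variance on `T − p` degrees of freedom (the
trace of the whitened residual-forming matrix).  `Ω̂` is always
block-diagonal over runs (noise independent between runs).  Solves go
through economy QR on the whitened model, never an explicit inverse of `Ω̂`
at full length; the closed form is verified on small instances.

* **identity** — `Ω̂ = I` (OLS).
* **ar1** — `Ω̂ = h₁ I + h₂ K` per run, where `K` has lag-`k` entries
  `0.2^k` and zero diagonal (the classic fixed-coefficient AR basis; the
  0.2 is exposed as a knob).  `(h₁, h₂)` are shared across runs and fitted
  by Fisher-scoring REML to the OLS residual covariance pooled over a voxel
  set (default: all voxels), the standard two-pass procedure.  Both
  components diagonalise in `K`'s eigenbasis, which is cached per run
  length, so each REML iteration is a few small matrix products.  The
  fixed 0.2 decay recovers a true lag-1 of 0.2 exactly but compresses
  stronger autocorrelation (≈0.33 fitted at a true 0.4); what matters
  downstream — the near-unbiasedness of the resulting ceiling — holds
  through lag-1 0.6 in the validation suite.
* **nonstationary** — `Ω̂ = diag(h_t)` per run, one variance per volume,
  fitted by Fisher-scoring (Newton-type) REML on the pooled residual
  covariance, robust-WLS style.  Weights are floored at 1e-6 of the mean
  initial variance.  Combining AR(1) and per-volume components in one
  estimation is deliberately not done.
* **r2r** — non-parametric: fit each run separately by OLS, use the
  across-run mean as `β̂` and the variance of that mean,
  `Σ_r (β̂ᵢᵣ − β̄ᵢ)² / ((n_r − 1) n_r)`, as `V̂ᵢᵢ`.  Requires every
  stimulus in every run (no imputation) and at least two runs.

REML stopping: relative step below 1e-6, at most 64 iterations.  Because
the pooled sample covariance is itself a Monte Carlo estimate, the step
norm can stall at a noise floor above the strict tolerance; a stalled step
below 1e-4 relative is accepted as converged, and only a step still above
1e-3 relative at the iteration cap raises an error (with the step trace
attached).  REML projections use the run's own design block as fixed
effects — equivalent to allowing run-specific response levels — which keeps
all REML algebra per-run while remaining a valid restricted likelihood.

Missing or censored volumes are not supported; rank-deficient designs raise
an error naming the dependent columns.

## Encoding models and metrics

The pRF weights are `P̂ = (XᵀX + λI)⁻¹ Xᵀ β̂` with the training mean of
`β̂` removed first (the removed mean is stored; an intercept column would be
the equivalent alternative).  Predictions `β* = X* P̂` are not re-centred:
any mean bias belongs in the metrics.  `λ` is a user grid (default
logspace 1e-2…1e4); no automatic selection, since the interaction of `λ`
with the ceiling is itself the object of study.  Scoring is columnwise over
voxels and identical to a per-voxel loop.

Metrics: sample correlation `ρ` (unbiased variances), predictive
`R² = 1 − Σ(β̂ᵢ−β*ᵢ)²/Σ(β̂ᵢ−β̂̄)²` (unbounded below on test data),
`D² = (n−1) σ̂²_β̂ (1−R²)` (exactly the squared prediction error), and
`γ = σ̂_β*/σ̂_β̂`.  For test responses centred to zero mean these satisfy
`R² = 2ργ − γ² − n/(n−1)·β̄*²/σ̂²_β̂`, which the suite checks to 1e-10;
`ρ` is scale-invariant, `R²` is not, and the λ maximising one need not
maximise the other.  Voxels with zero observed variance get NaN metrics
with an `undefined` flag instead of an exception.

## The simulation engine

What it emulates: a fast event-related experiment — every stimulus once per
run, inter-stimulus interval drawn uniformly from {2, 3, 4} TRs (TR 2.6 s),
6 runs — with responses `β = XP`, `P` standard normal, and feature matrices
with `N(0, 1/f)` entries so the response variance is ~1 and noise-variance
axes read directly as 1/SNR.  The HRF is a double gamma with response and
undershoot modes at exactly 6 s and 16 s and a 6:1 amplitude ratio, unit
peak, 32 s support, sampled at the TR; convolution never crosses run
boundaries.  SNR is the time-series signal variance (per voxel) over the
noise variance; in the run-effects scenario only the run-common signal term
counts as signal.

Noise scenarios (noise always generated independently per run):

1. **iid** — white Gaussian;
2. **ar1** — AR(1) with a given lag-1 coefficient (stationarity enforced:
   coefficient in [0, 1)), rescaled to the realised SD so the requested SNR
   holds exactly per run and voxel;
3. **nonstationary** — white noise with a seeded random 5% of volumes
   (default) scaled by a factor: either drawn uniformly from [1, factor]
   per affected volume (default) or fixed, chosen once per simulation;
   affected volumes are shared across voxels so the covariance structure is
   common to the pool;
4. **ar1_run_effects** — AR(0.25) noise plus a per-run response deviation
   `N(0, σ²_run)`, with `σ²_run` calibrated in closed form (root search for
   unbalanced halves) so the expected correlation between the noiseless
   mean responses of the two half-experiments is 0.6; calibration method
   and mixing proportion are recorded in the output.

Each replication draws a fresh `X`, `P` and noise; the event schedule is
fixed per scenario.  All randomness descends from the single scenario seed,
so identical specs give bit-identical outputs.  Defaults mirror the
reference study conditions: 126 training + 42 test stimuli, 128 features,
6 runs, 100 replications, 1000 voxels sharing one noise covariance (the
ceiling is reported for the first voxel; the pool exists for the pooled
covariance estimators).  Ceilings are always computed on the test stimuli.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: physiological noise (cardiac/respiratory),
spatial correlation between voxels, scanner drift and motion, HRF
variability across voxels, and stimulus repetitions within a run.

## Problem sizes used by the tests and the acceptance script

The validation experiments run at reduced stimulus/feature counts —
48 training + 24 test stimuli, 32 features, 6 runs — so the full suite
completes in a few CPU-minutes: per-level replication counts of 50 (i.i.d.
sweep), 25 (AR comparison), 15 per factor (non-stationary sweep), 40
(run-effects scenario), and 60 (regularisation study, which runs at the
full 128-feature, 126–1260-training-stimulus sizes since it is
response-level).  Pools are 1000 voxels wherever the pooled covariance
estimators are the thing under test, 200 otherwise.  The properties being
checked (bias patterns, band coverage, orderings, identities) are
size-invariant; only band widths change.

The regularisation study is run at the response level (`β̂ = β + ε` with
noise variance 0.5) rather than through the time-series GLM: its training
sizes extend far beyond what one 6-run design can hold, and the analytic
ceiling there uses the generative noise variance as the `V̂ᵢᵢ` plug-in.

## Numerical choices and edge cases

* QR-based least squares throughout; `(ΦᵀΦ)⁻¹` diagonals from the inverse
  triangular factor.
* Ridge solves by Cholesky of `XᵀX + λI`; `λ = 0` requires full column
  rank and the error suggests `λ > 0`.
* Monte Carlo ceilings chunk over voxels (128 at a time) to bound memory;
  a zero-variance noise-free draw (possible only when `σ̂²_β = 0`) counts
  as correlation 0.
* Per-replication failures inside a scenario are logged and counted
  (`n_failed`), never silently dropped.
* Percentiles are plain `numpy.percentile` at [5, 95]; with one
  replication they equal the single value.

## Known limitations

* The AR(1) variance model inherits the fixed-basis compression of strong
  autocorrelations; ceilings remain accurate in our validation range
  (lag-1 ≤ 0.6) but the fitted lag-1 itself is not a calibrated estimate.
* The run-to-run and split-half estimators need several runs to be stable
  (six runs already give them visibly wider bands than the parametric
  estimators) and require every stimulus in every run.
* Real-data preprocessing (motion correction, detrending, denoising
  regressors) is assumed done upstream; the GLM fits stimulus regressors
  only, with no drift or nuisance terms.
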