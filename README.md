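# fmrinc — test-data noise ceilings for voxelwise fMRI encoding models

Voxelwise encoding models predict a voxel's fMRI response to a stimulus from
a feature representation of that stimulus.  Their prediction accuracy is
bounded not only by how good the model is, but by how noisy the *test*
responses are: even the true generating model cannot correlate perfectly
with noisy measurements.  That bound — the **test-data noise ceiling** — is
what this package estimates, for people who fit encoding or pRF models and
want to report how much of the explainable signal their model captures.

## The model

Responses to single stimuli are estimated from the voxel time series `y`
with a GLM, `β̂ = (Φᵀ Ω̂⁻¹ Φ)⁻¹ Φᵀ Ω̂⁻¹ y`, where `Φ` is the HRF-convolved
design matrix and `Ω̂` the estimated noise covariance — the identity (OLS),
an AR(1)-structured mixture fitted by pooled REML, or a per-volume diagonal
(robust WLS).  Writing `σ̂²_β̂` for the variance of `β̂` across test stimuli
and `V̂ᵢᵢ` for the per-stimulus estimation variances, the ceiling on the
correlation between any model's predictions and the test responses is

    ρ̂_NC = sqrt( (σ̂²_β̂ − mean(V̂ᵢᵢ)) / σ̂²_β̂ ),      ρ̂_NC ∈ [0, 1],

clipped to 0 when the estimated signal variance is negative.  Three
estimators of this quantity are provided:

* **analytic** — the closed form above, with `V̂ᵢᵢ` from a parametric noise
  model or from the run-to-run variability of per-run estimates
  (`V̂ᵢᵢ = Σ_r (β̂ᵢᵣ − β̄ᵢ)² / ((n_r−1) n_r)`);
* **Monte Carlo** — resample noise-free signals and noisy measurements from
  the same variance split and take the median correlation (the analytic
  form without the algebra; the two agree to ~0.001);
* **split-half** — correlate responses estimated from two disjoint halves of
  the runs and correct for halving the data: the corrected reliability
  `2ρ/(ρ+1)` is the ceiling in the R² domain, and its square root is the
  correlation-domain ceiling.

An encoding model fit by ridge regression (`P̂ = (XᵀX + λI)⁻¹ Xᵀ β̂`) can
then be scored with `ρ`, predictive `R²` and `D²`, raw and relative to the
ceiling.  A simulation engine generates time series under four noise
scenarios (i.i.d., AR(1), non-stationary spikes, AR(1) plus run-to-run
response variability) with known ground truth, which is how every estimator
in the package is validated.

## Worked example

Simulate the hardest scenario — autocorrelated noise plus responses that
drift between runs — and compare all five ceiling estimators against the
ground truth:

```python
import fmrinc

spec = fmrinc.ScenarioSpec(
    scenario="ar1_run_effects", ar_coefficient=0.25, snr=1.0,
    n_stimuli_train=48, n_stimuli_test=24, n_features=32,
    n_voxels=200, n_replications=20, seed=0,
)
result = fmrinc.run_scenario(spec)
print(result.summary().round(3).to_string(index=False))
```

```
    estimator  nc_mean  nc_p5  nc_p95  true_mean  true_p5  true_p95    n
     identity    0.945  0.920   0.965      0.839    0.716     0.915 20.0
          ar1    0.938  0.914   0.961      0.842    0.713     0.921 20.0
nonstationary    0.955  0.942   0.972      0.795    0.623     0.917 20.0
          r2r    0.833  0.716   0.907      0.844    0.720     0.924 20.0
   split_half    0.843  0.770   0.925      0.844    0.720     0.924 20.0
```

`nc_mean` is each estimator's mean ceiling over 20 replications (with
[5, 95] percentiles), `true_mean` the matched ground-truth ceiling computed
from the known simulated responses.  The three parametric estimators
(identity, ar1, nonstationary) report ceilings around 0.94–0.96 when the
truth is ~0.84: they only account for measurement noise and miss the
run-to-run response variability.  The run-to-run (`r2r`) and split-half
estimators land inside the true ceiling's band — on real multi-run data
these are the estimators to trust.

On real data the same machinery runs from the shell:

```sh
fmrinc estimate --timeseries bold.nii.gz --events events.tsv \
    --runs-json runs.json --noise-model ar1 --out est/
fmrinc ceiling --beta-h5 est/beta.h5 --variance r2r \
    --methods analytic,split_half --out ceil/
```

and `fmrinc reproduce --figure fig4 --scale 0.25 --out out/` re-runs any of
the validation experiments (fig2–fig8) at a chosen fraction of the full
replication counts.

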