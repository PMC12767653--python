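# flashbci

Bayesian causal inference (BCI) modelling of the **sound-induced double-flash
illusion** across the visual field, built for studies that compare sighted and
low-vision observers.

When a single brief flash is paired with two beeps (condition `F1B2`),
observers often report two flashes. Whether — and where in the visual field —
this illusion appears depends on how the brain decides that flash and beeps
share a common cause. This package provides:

* a **generative BCI observer** for audiovisual numerosity reports (0–3),
* **maximum-likelihood fitting** of four model variants (full BCI, forced
  fusion, full segregation, flat-prior MLE cue averaging) under three
  decision strategies (model averaging, model selection, probability
  matching), with BIC model comparison and an R² fit-quality screen,
* a **synthetic-cohort generator** reproducing the psychophysics design
  (24 locations = 8 polar angles × 5°/10°/15° eccentricity, two eyes,
  conditions `FXBY` with exact repetition counts) including low-vision
  structure (per-location detectability, lapses, heterogeneous parameters),
* the **behavioural metrics** linking flash-detection accuracy to illusion
  strength and model fit quality.

## The model

On each trial the observer receives noisy measurements of flash and beep
numerosity,

```
x_V ~ N(s_V, σ_V),   x_A ~ N(s_A, σ_A),
```

holds a Gaussian numerosity prior `N(μ_P, σ_P)`, and infers whether the two
signals share a common cause (prior probability `p_common`):

```
p(C=1 | x_V, x_A) = p(x_V,x_A|C=1)·p_common /
                    [p(x_V,x_A|C=1)·p_common + p(x_V,x_A|C=2)·(1−p_common)]
```

Under a common cause the numerosity estimate is the reliability-weighted
average of both cues and the prior; under independent causes each modality is
estimated alone. A decision strategy combines the two conditional estimates
via the causal posterior, and the continuous estimate is rounded to the
nearest integer in [0, 3] — the simulated report. Model variants pin
parameters (fusion: `p_common=1`; segregation: `p_common=0`; MLE:
`p_common=1, σ_P=4000, μ_P=1.5`) and are scored by
`BIC = k·ln(n) − 2·logL`.

## Worked example

```python
import flashbci as fb

params = fb.ModelParams(p_common=0.8, sigma_v=0.35, sigma_a=0.2,
                        sigma_p=1.64, mu_p=1.5)

# response distribution for the illusion condition (one flash, two beeps)
print(fb.response_distribution("F1B2", params, "averaging").round(3))
# [0.053 0.589 0.358 0.   ]  -> 36% of trials report the illusory 2nd flash

# simulate a full participant at the experiment's design scale and refit
from flashbci.pipeline import _simulate_design_scale
trials = _simulate_design_scale(params, "averaging",
                                ("detection", "double_flash"), seed=7)
est = fb.BCIObserverFit(variant="bci", strategy="averaging",
                        n_restarts=3, n_nodes=61, seed=0).fit(trials)
print(len(trials), est.params_.p_common, est.params_.sigma_v)
# 816 0.740... 0.351...  -> the causal prior and visual noise are recovered
```

The printed distribution says a `p_common=0.8` observer with typical sighted
parameters reports "2 flashes" on roughly a third of illusion trials; the
refit recovers the generating causal prior (0.74 vs 0.8) and visual noise
(0.35 vs 0.35) from one participant's 816 trials. Single-participant
estimates of `p_common` scatter along a known trade-off with `σ_P` (see
`docs/methods.md`); median errors across replicates are much tighter.

Sklearn-style estimators (`BCIObserverFit`, `ModelSelector`,
`AuditoryNoiseCalibrator`) expose `fit` / `predict_proba` /
`get_params`; the equivalent functional API (`fit_model`, `compare_models`,
`calibrate_sigma_a`) is also available.

## Command line

```bash
flashbci simulate --seed 1 --out runs/sim         # cohort -> trials.csv
flashbci fit runs/sim/trials.csv --out runs/fits  # per-participant fits
flashbci compare runs/fits --out runs/table.csv   # BIC comparison table
flashbci metrics runs/sim/trials.csv --out runs/m # accuracy, correlations
flashbci recover --seed 1 --out runs/recovery.json
flashbci pipeline --seed 1 --out runs/full        # everything
```

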