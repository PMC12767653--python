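# Methods

## The observer model

Each trial presents `s_V ∈ {0, 1}` flashes and `s_A ∈ {0, 1, 2}` beeps
(condition code `FXBY`). The observer receives noisy measurements
`x_V ~ N(s_V, σ_V)` and `x_A ~ N(s_A, σ_A)` in numerosity units, holds a
Gaussian prior `N(μ_P, σ_P)` over stimulus numerosity, and a prior
probability `p_common` that the two signals share one cause.

The two cause-conditional likelihoods have closed forms (a rank-one
correlated bivariate Gaussian for the common cause; a product of two widened
Gaussians for independent causes); both are validated against numerical
quadrature in the test suite. The causal posterior follows by Bayes' rule
and is evaluated on the log-odds scale, which is exact at the `p_common = 0`
and `1` boundaries.

Conditional numerosity estimates are posterior means: the reliability-
weighted average of `x_V`, `x_A` and the prior under a common cause, and
the prior-regularised single-cue estimate under independent causes (the
flash report uses the visual cue; the beep report the auditory one).
Three decision strategies map the causal posterior π to a report:

* **averaging** – report `disc(π·fused + (1−π)·alone)`;
* **selection** – report `disc(fused)` if π > 0.5, else `disc(alone)`;
* **matching** – a π / (1−π) mixture of the two discretised reports.
  The likelihood uses the analytic mixture rather than per-trial sampling so
  that the fitted objective is deterministic; the forward simulator draws
  the cause per trial.

`disc(·)` rounds half-up and clips to [0, 3], the response range of the
task. The experiments themselves do not specify how continuous estimates
become discrete reports; round-half-up with clipping is the convention in
numerosity-judgment modelling and is fixed here (ties at exactly .5 go up).

### Response distributions

The per-condition distribution over reports 0–3 marginalises the sensory
noise on a deterministic tensor-product grid: 101 Gauss-weighted nodes per
axis spanning ±5σ (weights ∝ the standard normal density, renormalised;
truncation error < 1e-6 of the mass). Deterministic marginalisation keeps
the likelihood surface smooth for optimisation. A seeded Monte-Carlo route
(default 10⁵, typically run at 10⁶ samples in validation) exists purely as
an independent cross-check; grid and simulation agree to < 0.005 per
category.

Detection-task trials are yes/no reports coded as counts 1/0 and scored as
`p(report ≥ 1)` vs `p(report = 0)` — the same numerosity observer, with the
silent auditory channel at `s_A = 0`. A consequence worth knowing: a
strongly integrating observer (`p_common` near 1) with large `σ_V` is pulled
toward "no flash" by silence, so modelled F1B0 detection can drop well below
ceiling even at full stimulus detectability. This is a real property of the
model, not an artefact.

## Fitting

Main fits fix `σ_A = 0.2` (the auditory calibration value, below) and
`μ_P = 1.5`, and free parameters per variant:

| variant | free | fixed |
|---|---|---|
| BCI | `p_common, σ_P, σ_V` | — |
| forced fusion | `σ_P, σ_V` | `p_common = 1` |
| full segregation | `σ_P, σ_V` | `p_common = 0` |
| MLE | `σ_V` | `p_common = 1, σ_P = 4000, μ_P = 1.5` |

Bounds: `p_common ∈ [0, 1]`, `σ_V ∈ [0.01, 10]`, `σ_P ∈ [0.01, 5000]`.
The negative log-likelihood collapses trials to per-condition response
counts, applies a per-trial probability floor of 1e-6 (floor hits are
reported in diagnostics), and is minimised by bounded Nelder–Mead in a
transformed space (log for the σ parameters) from (a) the three best
corners of a deterministic coarse scan over the free-parameter box and
(b) `n_restarts` seeded uniform starts, followed by a polish restart from
the winner. The coarse scan matters: the likelihood is near-flat along a
`p_common`–`σ_P` ridge (a weakly identified trade-off — a small causal prior
with a wide numerosity prior mimics a large causal prior with a narrow one),
and random restarts alone can stall in the wrong basin. With the scan,
fitted solutions are at least as likely as the generating truth in every
recovery replicate we run.

Model comparison fits the BCI model under all three strategies and the
three reduced variants once (their strategies coincide when `p_common` is
pinned at 0 or 1); the winner is the lowest-BIC variant,
`BIC = k·ln(n_trials) − 2·logL`. Fit quality is screened by
`R² = 1 − SS_res/SS_tot` computed over per-cell response-category
proportions (cell = condition × location × eye; detection cells contribute
the yes/no split, numerosity cells all four categories), with `SS_tot`
about the grand mean of the observed proportions; the screen threshold is
R² ≥ 0.8. Because the observer has no spatial dimension, predictions are
constant across locations — spatial heterogeneity in the data therefore
lowers R², which is exactly what makes the screen informative for
low-vision-like data.

A note on the `p_common = 1` regime: with `σ_A = 0.2` the numerosity prior
contributes almost nothing to the fused estimate, so the flat-prior MLE
variant reproduces forced fusion's likelihood with one fewer parameter and
wins BIC whenever the truth is pure fusion. Model-recovery claims at
`p_common = 1` are therefore stated for the fusion family (forced fusion or
MLE) rather than forced fusion alone.

### Auditory calibration

`σ_A` is estimated from beep-count reports of the binocular beep-detection
task with a reduced observer: independent causes, unisensory estimation,
`σ_V = 0.4`, `μ_P = 0`, `σ_P = 4000` fixed, leaving a 1-D ML fit. A
log-spaced scan brackets the optimum before local refinement; ties on
likelihood plateaus (e.g. error-free data) resolve to the smallest `σ_A`.

## Synthetic cohorts

The generator reproduces the experiment's structure exactly: 24 locations
(8 polar angles × 5°/10°/15° eccentricity); monocular flash detection
(F1B0 ×5 + F0B0 ×1 per location per eye → 144 trials/eye), monocular
double-flash (F1B2 ×10 + F1B1 ×1 → 264 trials/eye), binocular beep
detection (6 conditions ×3 → 432 trials); trial order shuffled per eye,
reproducible by seed.

Low-vision structure is emulated minimally: each `(location, eye)` carries a
Bernoulli detectability — an undetected flash reaches inference as
`s_V = 0` — plus an optional uniform-guess lapse rate. Cohort defaults draw
per-participant parameters from truncated normals centred on the magnitudes
typical of this paradigm (sighted: `p_common` 0.81, `σ_P` 1.64, `σ_V` 0.35;
low vision: 0.63 / 1.04 / 0.32), with between-participant SDs set to the
reported standard errors scaled by √N; decision strategies are sampled with
prevalences 59/24/18% (averaging/selection/matching). Low-vision observers
draw an "invisible fraction" of locations uniformly from 0.1–0.6, with
detectability 0.05–0.4 at invisible and 0.85–1.0 at visible locations, and
lapse rates up to 0.05. These cohort-level distributions are configuration
choices — the underlying studies publish no quantitative distribution of
field loss — and are stated here so they can be changed knowingly.

What the generator does **not** emulate: stimulus rendering and timing,
fixation instability or eye movements, strategy switching within a
participant, serial dependencies, or non-Gaussian sensory noise. Passing
recovery tests therefore show the pipeline is correct and well-calibrated
for data that satisfy the model's assumptions, not that real low-vision
data do.

## Determinism and seeds

Every stochastic stage draws from a child seed derived by SHA-256 hashing of
(master seed, stage name, unit id), all below 2³¹; adding participants never
perturbs existing ones, and identical configurations byte-reproduce all
pipeline outputs.

## Problem sizes

Validation experiments run at the study's design scale: 816 flash-task
trials per participant (2 eyes × (240 F1B2 + 24 F1B1 + 120 F1B0 + 24
F0B0)), 20 replicates for recovery statistics. Fits in the recovery and
pipeline experiments use 3 random restarts plus the deterministic scan and
a 61-node marginalisation grid — empirically indistinguishable from the
101-node default for these smooth 1–3 parameter problems — while the
estimator defaults keep 10 restarts and 101 nodes.

## Known limitations

* `p_common` and `σ_P` trade off; single-participant point estimates
  scatter along the ridge even when the fit is optimal. Median errors
  across replicates (reported by the recovery experiment) are the honest
  summary of what the design identifies.
* The R² screen conflates spatial heterogeneity with model misfit — by
  design, but it means R² is not a pure goodness-of-sensory-model measure.
* No lapse parameter is fitted (generation supports lapses; fitting them is
  a robustness experiment, not the default), so heavy-lapse observers
  inflate fitted `σ_V`.
* Detection trials share the numerosity observer; there is no separate
  detection-theoretic (d′) channel.
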