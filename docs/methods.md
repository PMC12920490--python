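# Methods

This note documents the models and procedures implemented by `interobattery`,
the defaults chosen where the underlying scoring traditions leave room, and
what the synthetic-data generator does and does not emulate.

## Physiological features

**R-peak detection.** The detector follows the classic Pan–Tompkins chain:
zero-phase band-pass at 5–15 Hz (2nd-order Butterworth), differentiation,
squaring, 150 ms moving-window integration, then an adaptive dual threshold
with running signal/noise peak estimates, a 200 ms refractory period, and a
searchback pass for long gaps (> 1.66 × the running RR average). Each
detection is refined to the raw-signal maximum within ±50 ms so reported times
sit on the R wave. Flat input returns an empty series with a warning; traces
shorter than 2 s are rejected.

**Tachogram.** RR intervals between consecutive detections. Optional artifact
correction (off by default) replaces intervals outside 0.3–2.0 s or deviating
more than 30% from a 5-point running median by cubic interpolation over the
surrounding good intervals. It is off by default because the upstream
acquisition pipeline being mirrored describes no beat correction.

**Frequency-domain HRV.** RR (ms) is cubic-spline interpolated onto a uniform
4 Hz grid and detrended. The default detrend is the smoothness-priors method
(second-difference prior, λ = 500), matching the behaviour of the common HRV
toolchains; plain linear detrending is available via `detrend="linear"`. The
PSD is a Welch periodogram (Hann window, 120 s segments or the full record if
shorter, 50% overlap) integrated over LF = 0.04–0.15 Hz and HF = 0.15–0.4 Hz.
The LF lower bound follows the standard task-force bands. `hf_log_power` is
the natural log of the *integrated* HF power in ms² (integrated band power
was chosen over peak density; the alternative reading of "log power" as a
density is not used). Records spanning less than 60 s, or with numerically
zero HF power (a constant tachogram), raise errors rather than returning
meaningless spectra. Mean HR is `60 / mean(RR)`.

**Breath frequency.** The respiration trace is low-pass filtered at 1 Hz;
inspiratory peaks are gated by prominence relative to the trace SD (making
the result invariant to amplitude scaling), each cycle onset is the last
positive-going mean-crossing before its peak, and breath frequency is the
number of complete onset-to-onset cycles divided by the time they span.

## Interoceptive scores

**Heartbeat detection (tapping).** Trials are assigned an HR category from
their own mean HR with cut-points at 69.75 and 94.25 beats/min; the printed
category inequalities are strict on both sides, so the boundary values
themselves are assigned to the middle category. A tap is correct when its
latency after an R-peak falls inside the category's window; the windows are
**not fixed by the scoring tradition** and default to slow [100, 500] ms,
mid [100, 400] ms, fast [50, 300] ms — they are configurable and the accuracy
formula itself is window-agnostic. Matching is one-to-one and greedy by
smallest latency, so neither a tap nor a beat can be counted twice. Matched
counts are pooled across trials and
`acc_d = 1 − |recorded − matched| / recorded`, clipped to [0, 1] (clipping
only guards pathological inputs: after one-to-one matching the matched count
cannot exceed the beat count).

**Heartbeat counting.** Per-trial score `1 − |recorded − counted|/recorded`,
averaged over the (by default exactly four) trials. Deliberately *not*
clipped: counting more than twice the recorded beats drives the score
negative, exactly as the formula reads.

**Awareness.** `aw = |acc_norm − conf_norm|` with min-max normalisation of
each measure *within the analysed cohort* (no fixed scale bounds exist for
accuracy, so cohort-relative normalisation is the only option that uses both
empirical ranges; it is computed within-task, not pooled across tasks). A
zero-range vector raises an error naming the degenerate measure.

**Questionnaires.** MAIA (32 items → 8 subscales, 0–5 scale, mean
aggregation, items 5–9 reverse-coded) and BPQ-22 (three factors, 1–5 scale,
sum aggregation) are scored through editable YAML item maps. The shipped MAIA
map is the published v1 assignment. The shipped BPQ map is a **documented
placeholder block assignment** (the published item→factor table is not
bundled); replace `data/bpq_map.yaml` for real scoring. Missing items: a
subscale with more than 20% of its items missing scores NaN; otherwise the
mean of available items is used (prorated to the item count under sum
aggregation).

## Exteroceptive scores

**Body image.** `delta_ar = mean(BMI of silhouettes chosen as own physique)
− weight/height²`. The silhouette→BMI table ships as an editable YAML with
approximate published values.

**Race-model violation AUC.** Empirical CDFs of a bimodal condition and its
two unimodal parents are evaluated at the bimodal condition's 5th–100th
percentiles (steps of 5, linear-interpolated quantiles). The race bound is
`min(1, F_uni1 + F_uni2)` — capped at 1 because the raw sum exceeds 1 at late
times and would otherwise manufacture negative violations. The AUC is the
trapezoidal integral of `max(0, actual − bound)` over the percentile axis as
fractions. Quantile-based evaluation avoids choosing a time-bin width and is
invariant to shifting all RTs by a constant.

**Psychometric fits.** All fits are binomial maximum likelihood.
Simultaneity judgments use a Gaussian bump `a·exp(−(x−μ)²/2σ²)` with
amplitude a ∈ (0, 1]; the JND is σ. Temporal-order judgments use a
cumulative Gaussian `Φ((x−μ)/σ)`; the JND is the 75%–25% half spread
`σ·Φ⁻¹(0.75) ≈ 0.6745σ`. Both conventions are explicit in the code and easy
to change. On non-convergence or runaway slopes (perfect separation) the TOJ
fit falls back to a ridge-penalised probit (quadratic penalty on the slope,
weight 1e-3) and flags the result.

**Peripersonal-space PSE.** The Spearman–Kärber midpoint estimator on
proportions made monotone by pooled-adjacent-violators, extended with p = 0 /
p = 1 one step beyond the tested range. The estimator consumes a
(level, n presented, n positive) table; when only per-level RTs are
available, the caller must derive response proportions first (e.g. by
thresholding RT facilitation per level) — that adapter is a stand-in
convention, not part of the estimator.

**Sum of confusion.** `SC = Σ |p_crossed − p_uncrossed|` over a fixed
symmetric SOA grid (−400…400 ms, 10 ms steps) evaluated from the two fitted
TOJ curves. Absolute differences are used because a signed cumulative sum can
cancel to zero for curves that clearly diverge, contradicting SC's role as a
divergence measure. SC ≥ 0 with equality iff the curves coincide on the grid.

**Mental-rotation slope.** OLS slope (ms/degree) of the per-angle *median*
correct-trial RT against rotation angle; medians because simple-RT
distributions are right-skewed.

## PLSR with nested leave-one-out cross-validation

The engine is a univariate-outcome NIPALS PLS1 with a cumulative coefficient
path: one decomposition at `k_max` yields the regression coefficients for all
K = 1..k_max (using the unit-triangularity of PᵀW), which is what makes the
fully nested procedure and its permutation null affordable. The hot loops are
JIT-compiled (numba); the same algebra also exists as a plain-NumPy reference
implementation, and the two are cross-checked against each other, against
OLS at K = p, and against scikit-learn's PLSRegression in the test suite.

Choices that matter:

* **Standardisation inside every training fold.** Predictors are on wildly
  different scales (ms, %, bpm, questionnaire units) and PLSR is
  scale-sensitive, so X columns are z-scored and y centred from the training
  rows only; the held-out row never contributes to standardisation, K
  selection, or fitting (a leakage test asserts that changing a held-out y
  never changes its own prediction).
* **K selection.** The inner leave-one-out loop picks the K with smallest
  mean squared prediction error; ties break toward the smallest K
  (parsimony). Inner folds with a constant column are skipped.
* **Reported weights.** One weight per predictor, from a refit on all rows at
  the *modal* outer-fold K (when all chosen K are distinct, the floor of the
  median is used). Fold-averaged weights are not reported.
* **Permutation inference** (default n_perm = 1000, minimum 200 so the 95%
  null quantiles are estimable). The model-level p-value for r uses the
  add-one convention `p = (1 + #{r_null ≥ r_obs}) / (1 + n_perm)`. Each
  permutation reruns the outer leave-one-out with the per-fold K held at the
  observed choices rather than re-selecting K — a deliberate reduction that
  keeps hundreds of permutations tractable while preserving the fold
  structure; full re-selection per permutation is available via
  `reselect_k=True`. Weight nulls refit the full-data model at the observed
  modal K; a weight is significant when outside its null [2.5%, 97.5%]
  interval. Measured on null cohorts (100 replicates, n = 60, p = 21,
  n_perm = 500), the per-weight flag rate is ≈ 0.05 and the model-level
  type-I error ≈ 0.04, so the reduced null is well calibrated.
* **Missing predictors** are median-imputed (no outcome information is used).

## Two-step pipeline

Step 1 fits the eight SF-36 subscale models from the 21 interoceptive +
physiological predictors. A model is significant when its permutation p for r
is below α = 0.05; no multiple-testing correction is applied across the eight
models by default (a Bonferroni switch exists). The retained set is the
*union*, over significant models, of predictors with significant weights
(a per-model retention mode is available). Step 2 refits each significant
outcome on retained + the 14 exteroceptive variables. If no step-1 model is
significant the pipeline exits early with a report saying so. The variable
registry guards the whole chain: a missing registered column aborts the run
naming the column, so predictors can never be dropped silently. With a fixed
cohort table, configuration and seed the entire report is bit-reproducible
(all streams are spawned from the one master seed).

## Synthetic-data generator

The generator provides ground-truth oracles for every stage:

* **R-peak trains** with instantaneous RR
  `60/HR + a_LF sin(2π·0.1t) + a_HF sin(2π·0.25t)` — planted spectral lines in
  the standard LF/HF bands.
* **ECG traces**: a Mexican-hat (Ricker) kernel of ~80 ms support at each
  planted R time plus optional white noise — the simplest morphology the
  detector chain should handle; planted times travel in the signal metadata.
* **Psychometric trials**: binomial responses from a lapse-scaled cumulative
  Gaussian or Gaussian bump.
* **Reaction times**: ex-Gaussian unimodal draws (defaults μ = 350 ms,
  σ = 50 ms, τ = 80 ms — typical simple-RT values, configurable); each
  bimodal RT is the minimum of two fresh independent unimodal draws, so the
  race bound holds exactly unless a coactivation gain is subtracted.
* **Cohorts**: predictors drawn from realistic truncated-normal marginals
  (per-variable means/SDs/bounds in `DEFAULT_PREDICTOR_DISTRIBUTIONS`),
  outcomes built as sparse linear combinations of *standardised* predictors
  plus Gaussian noise on the latent scale, affinely mapped to 0–100
  (offset 50, scale 15) and clipped — SF-36 subscales are bounded. The
  planted coefficient map is stored beside the table.

The reference recovery scenario (`demo_cohort_spec`) plants MAIA
self-regulation/trusting analogues on the two role-limitation subscales, mean
HR on energy/fatigue, and the body-image discrepancy as a purely
exteroceptive contribution, each at latent noise SD 0.8 (per-outcome
R² ≈ 0.6).

**What the generator does not emulate** — and hence what passing tests do and
do not show: predictor marginals are independent truncated normals (no
realistic inter-predictor correlation structure, e.g. between the MAIA
subscales), effects are linear in standardised predictors, outcomes have
Gaussian latent noise, ECG morphology has no P/T waves, there is no
respiratory–cardiac coupling, and questionnaire item-level response processes
are not modelled. Recovery and calibration results therefore validate the
*estimators and inference machinery*, not the substantive behaviour of the
battery on real cohorts.

## Problem sizes and runtime

The test suite and `scripts/acceptance.py` use cohorts of n = 60 with 21/35
predictors, 200–500 permutations per model, 25 replicate cohorts for
end-to-end recovery and 100 replicates for null calibration, 200 trials per
level for psychometric recovery, and 5000 trials per condition for
race-model checks; one full acceptance run takes about 1.5 minutes on one
CPU. These sizes are the package's chosen reference conditions; everything
scales up via the obvious parameters.

## Known limitations

* The tapping windows and the BPQ item map are configurable conventions, not
  reproductions of any specific lab's values; results depending on them
  should be reported together with the configuration used.
* The permutation null for r preserves the observed per-fold K by default;
  with very adaptive K selection the full `reselect_k=True` null is the
  safer (much slower) choice.
* With effects planted on a subset of outcomes and α = 0.05 per model with no
  multiplicity correction, the probability that *no* null outcome is flagged
  is bounded by 0.95^(number of null outcomes); exact recovery of the
  significant-outcome set is correspondingly capped (≈ 0.77 with five null
  outcomes) — a property of the uncorrected testing scheme, not an estimator
  defect.
* Single-outcome PLS1 only; sparse PLS, O-PLS and multi-outcome PLS2 are out
  of scope, as are time-domain/nonlinear HRV indices.
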