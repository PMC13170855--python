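# Methods

This note records the models, conventions, and design choices behind
`trajaki`, in enough detail to reimplement or audit every stage. It states
no empirical claim that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Window construction

**Grid.** For each admission the analytic series starts at the first
creatinine measurement taken at or after 48 h before ICU admission
(earlier values are dropped) and ends at the earliest of KRT initiation,
death, or ICU discharge. Day *d* covers hours [24d, 24(d+1)) after the
anchor; the day containing the end event is the last grid day, and an event
falling exactly on a day boundary ends the grid on the previous day. When a
day holds several measurements the **last** one is used (most recent kidney
state; no standard convention exists). Admissions are excluded for ESKD,
for KRT/death within 24 h of ICU admission, or for fewer than two in-window
measurements; exclusion counts are returned for flow reporting.

**Imputation and perturbation.** Unobserved interior days are linearly
interpolated; unobserved edge days copy the nearest observed value.
Every non-observed creatinine value (interpolated or padded) is perturbed
uniformly within measurement-uncertainty bounds: ±11.4% of the value at
≥ 1 mg/dL, ±0.114 mg/dL below 1 mg/dL, floored at 0.1 mg/dL to keep eGFR
defined. The uniform distribution is a choice — only the bounds are
prescribed; a boundary value of exactly 1.0 mg/dL uses the relative rule.
Observed values are never altered. eGFR is always recomputed from the
(possibly perturbed) creatinine together with age and sex via the CKD-EPI
2021 race-free equation, so the two input channels can never disagree.

**Padding and windows.** Five copies of the day-0 creatinine, each
independently perturbed by the same noise model, are prepended; rolling
seven-step windows then end at each grid day from day 1 onward, so an
admission with D grid days yields D − 1 windows and the k-th window carries
max(0, 5 − (k − 1)) padded steps. Outcome labels use half-open intervals
closed on the right: an event at time t counts for horizon h iff
t_end < t ≤ t_end + h, where t_end is the grid time of the window's final
step (an event exactly h hours later counts).

**Split.** Windows are partitioned uniformly at random into train (80%),
validation (5%), and test (15%) with counts equal to the rounded targets.
The split is at window level, treating each instance as independent; an
admission-level split for leakage checks can be obtained by grouping on
`admission_id` in the windows table.

## 2. Clinical rules

eGFR (mL/min/1.73 m²) = 142 · min(Scr/κ,1)^α · max(Scr/κ,1)^−1.200 ·
0.9938^age · (1.012 if female), with κ = 0.7/0.9 and α = −0.241/−0.302 for
female/male.

KDIGO staging over a seven-step window uses the **within-window minimum**
as the baseline (a rolling 7-day baseline; the window length was chosen to
match the KDIGO 7-day interval). With c_T the final value, ratio =
c_T/baseline, and the 48-h rise = c_T − min(last three steps) (48 h = two
daily steps): stage ≥ 2 iff ratio ≥ 2.0; else stage 1 iff the 48-h rise
≥ 0.3 mg/dL or 1.5 ≤ ratio < 2.0; else no AKI. Padded steps participate in
the baseline minimum — they replicate the earliest measurement, so this
mirrors what the model sees. Staging is computed on exactly the values fed
to the model (after perturbation and padding).

The composite anomaly-detected-AKI rule is a conjunction: strictly rising
final creatinine (c_T > c_{T−1}) and final-step score at or above the
threshold (s_T ≥ τ, inclusive).

## 3. Anomaly transformer

Architecture (defaults): input projection 2 → d_model = 32 with learnable
positional embeddings; 2 layers, each with 2-head anomaly attention
(per-head dimension 16), output projection, residual + layer norm, and a
2× feed-forward block; linear read-out back to 2 channels. Per layer and
head the **series association** S is the softmax attention map and the
**prior association** P_ij ∝ exp(−(i−j)²/2σ_i²) row-normalized, with σ_i
predicted per position by a linear head and bounded to [1.0, 3.0] via a
scaled sigmoid. The bounds matter: with an unbounded (or very small) σ the
symmetric KL between P and S rows can saturate near its ε-floor ceiling
(probabilities are floored at 1e-8 before logs), and the score's
softmax(−AssDis) factor collapses to an argmax at an initialization-
dependent step. Inputs are z-normalized per variable with training-set
statistics that are frozen thereafter.

**Training.** Mini-batch minimax with adaptive first-order updates
(Adam semantics; lr 2e-4, batch 256, max 40 epochs, patience 5 on the
validation reconstruction MSE, best-validation weights restored). Each
batch applies both phases in one update: the prior-side loss
λ_disc · mean AssDis(P, S·stopgrad) (λ_disc = 3.0) pulls P toward S, and
the series-side loss −λ_push · mean AssDis(P·stopgrad, S) (λ_push = 0.05)
pushes S away from P; both phases share the reconstruction term. The
asymmetry is deliberate: at seven steps a symmetric push lets the series
association drift arbitrarily far from the Gaussian-kernel family exactly
at rare inputs, which makes the per-step discrepancy profile — and hence
the score — unstable across initializations. With the asymmetric weights
the discrepancy stays small and informative and the score is dominated by
reconstruction error with a smooth discrepancy modulation. Labels are never
seen during training or calibration.

**Scoring.** Per window, score_i = softmax_i(−AssDis) · recon_i with
recon_i the squared reconstruction error averaged over the two channels;
s_T is the last entry. Batch scoring equals per-window scoring elementwise.
τ is the q-th percentile (linear interpolation) of training s_T, q = 95 by
default, with 90/97.5/99 used in sensitivity runs; it is calibrated once
and reused for internal and external evaluation without refitting or
recalibration. Checkpoints serialize weights, configuration, normalization
statistics, and the threshold in a single archive with a schema string.

## 4. Evaluation conventions

- Score-by-stage comparisons and score-by-outcome comparisons use the
  creatinine-rising subset (the composite rule's domain); two-sided
  Mann–Whitney U, exact for tie-free groups of ≤ 20, asymptotic with tie
  correction otherwise. No multiplicity adjustment (p-values are reported
  unadjusted).
- AUROC is computed on rising windows only; degenerate label sets yield an
  explicit undefined marker, never a number.
- Accuracy/F1/precision/recall are computed on *all* windows (including
  non-rising ones) for the four strategies; F1 = 0 when precision + recall
  = 0.
- Event capture at horizon h uses horizon-specific outcome-positive windows
  as the denominator and decomposes "either" into anomaly-only, stage≥2-
  only, and both. These are window-level rule-positivity rates among
  outcome-positive windows, not patient-level sensitivity.
- Stratum odds ratios cross-classify anomaly detection × stage ≥ 2 with
  anomaly−/stage− as reference; each OR equals the 2×2 cross-product
  against the reference (numerically identical to the saturated logistic
  model, which the tests verify via statsmodels), with Wald 95% CIs on the
  log scale and Haldane–Anscombe 0.5 correction (flagged) for zero cells.
- Sensitivity analyses: complete-case (windows from admissions with no
  interpolated days); thresholds recalibrated at alternative upper-tail
  percentiles with accuracy/F1/precision/recall per horizon; effective
  window lengths 2–6 days by keeping the most recent steps and left-padding
  with unperturbed copies of the earliest retained step, rescored with the
  frozen model.
- Representative examples: one window per cell of {stage ≥ 2, not} ×
  {anomaly, not}, anomaly cells paired with near-term KRT and maximal s_T,
  non-anomaly cells with no near-term KRT and minimal s_T; the KRT pairing
  is relaxed (with a logged notice) before a cell is dropped.

## 5. Synthetic cohort generator

The generator defines the package's reference study conditions; it emulates
the *statistical structure the analysis assumes*, not any real database's
joint distribution.

**Population.** Age ~ N(65, 16²) clipped to [18, 99]; 56% male. Baseline
creatinine is lognormal (median 0.9 mg/dL, log-sd 0.35) with a 12%
chronically-elevated subgroup (median 2.2 mg/dL, log-sd 0.25) representing
CKD — the case mix in which AKI hides from ratio-based staging. 1% of
admissions carry an ESKD flag solely to exercise the exclusion filter.
Length of stay ~ Gamma(4, mean 7 days), minimum 2.

**Trajectories.** Four regimes with probabilities 0.60/0.15/0.10/0.15:
stable (multiplicative random walk, daily CV 8%), monotonic rise (stable
until a random onset, then daily ratios in [1.15, 1.35]), fluctuating
(alternating ±20–40% steps), recovery (1–3 day rise at 1.2–1.5×/day, then
geometric decay toward baseline at 0.7–0.9/day). Values are clipped to
[0.2, 20] mg/dL. Values are generated on an hourly clock with daily lab
draws at jittered times (occasionally two per day, so the last-in-bin rule
is exercised); 70% of admissions anchor up to 48 h pre-ICU; each post-
anchor day is unmeasured with probability 0.10, giving roughly half of
admissions at least one missing day at the default length of stay.

**Outcomes.** Daily hazards are logistic. The linear predictor is
rising-gated: gate · [1.5·(ratio−1)₊ + 1.5·log(creat) + 2.0·(CKD)] +
0.5·(day-over-day rise)₊ for KRT, with the gate 1.0 while creatinine is
non-decreasing and 0.2 while falling (a recovering kidney defers dialysis);
mortality uses weaker slopes (0.5/0.5/0.2 boost 0.5) — kidney trajectories
predict dialysis better than death. On top of the trajectory-linked hazard,
a trajectory-*independent* constant hazard carries 35% of KRT and 50% of
death events: real ICU outcomes are substantially unpredictable from
creatinine alone, and without this component a ratio threshold would be a
near-perfect oracle, which no published evaluation shows. Intercepts for
both components are calibrated by bisection against the sampled
trajectories so realized event fractions match the configured targets
(KRT 3%, mortality 7%); the KRT intercept is calibrated on death-truncated
series so the competing event does not bias the marginal. Death truncates
the observation series; KRT does not (creatinine is still drawn on KRT).

**What the generator does not emulate — and what passing tests therefore
do not show.** No urine output, vitals, comorbidities, or fluid-balance
artifacts; no informative observation patterns (missingness is independent
of severity); one admission per patient; and only short-memory dynamics —
the hazard depends on the last two days' values and the cumulative ratio,
so truncating window history costs little discrimination here, and the
strong window-length dependence reported on real ICU data is *not*
reproduced by this cohort. Passing the qualitative acceptance tests shows
the pipeline's machinery reproduces the analysis' directional findings
under these assumptions; it is not evidence about real EHR data.

## 6. Validation scale and stochastic-pattern testing

The reference validation runs 2,000 admissions (≈ 11,500 windows,
≈ 9,100 training) with 25-epoch training — about 30 s per model on one
CPU. Unsupervised detectors this small are initialization-sensitive:
occasional inits produce a detector whose score grades severity weakly.
Directional acceptance checks are therefore asserted on the majority of a
three-detector panel (seeds 0, 1, 2, all reported, none discarded);
rank-based stage and outcome comparisons and the stratum ORs are computed
on all windows of the cohort for statistical power and estimate stability,
while AUROC, strategy metrics, and capture use the held-out test split.
Exact rule constants, perturbation bounds, windowing counts, split counts,
threshold calibration, and all oracle equivalences are deterministic and
tested exactly.

## 7. Numerical conventions

- Percentiles: linear interpolation between order statistics.
- KL terms: probabilities floored at 1e-8 before logs.
- Perturbed creatinine floored at 0.1 mg/dL.
- Degenerate inputs (empty strata, single-class labels, empty exemplar
  cells) yield explicit undefined markers or logged notices, never silent
  numbers.
- All randomness flows from named integer seeds (cohort, preprocessing,
  split, model); identical configuration implies byte-identical outputs.

## 8. Known limitations

Beyond the generator's scope (above): the autodiff engine is minimal and
CPU-only; training at much larger scales would need batching beyond what a
tape per mini-batch allows comfortably. The seven-step format hard-codes
the KDIGO-aligned window; other window lengths enter only through the
truncation sensitivity analysis. The KDIGO implementation is creatinine-
based only (no urine-output criteria, no KRT-based stage 3), and stage ≥ 2
is not subdivided.
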