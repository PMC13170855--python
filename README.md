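# trajaki — trajectory-based anomaly detection of acute kidney injury

`trajaki` asks whether short daily trajectories of serum creatinine and
estimated GFR carry risk information that fixed creatinine thresholds miss.
Static KDIGO criteria stage acute kidney injury (AKI) from threshold
crossings (a rise ≥ 0.3 mg/dL within 48 h, or 1.5×/2.0× the baseline), but
in the ICU the baseline is often unknown, dilution can mask injury, and the
*shape* of kidney function over time — rapid monotonic rises, oscillation,
incomplete recovery — is prognostic in itself. The package implements an
unsupervised, label-agnostic alternative: learn what typical multi-day
creatinine–eGFR trajectories look like, and flag windows whose final step is
atypical.

It is aimed at clinical data scientists and methods researchers who want a
tested, reproducible reference implementation of this analysis that runs
end-to-end on synthetic data (large ICU EHR databases are credentialed-access
and are neither bundled nor required).

## What it implements

**Windowing.** Each admission's creatinine series (starting up to 48 h
before ICU admission, ending at KRT, death, or discharge) is resampled to a
24-hour grid; missing days are linearly interpolated; non-observed values
are stochastically perturbed within measurement-uncertainty bounds
(±11.4% at ≥ 1 mg/dL, ±0.114 mg/dL below); five noisy copies of the first
measurement are prepended; and rolling seven-step, two-variable windows
(creatinine, CKD-EPI 2021 race-free eGFR) are labeled with KRT/death
occurrence within 24/48/72/96 h of the final step.

**Model.** An anomaly transformer over the 7×2 windows: each attention
layer carries a data-driven *series association* S (softmax self-attention)
and a *prior association* P (row-normalized Gaussian kernel over inter-step
distance with learnable per-position scale σ ∈ [1, 3]). The per-step
**association discrepancy** is the symmetric KL divergence between the
P and S rows, averaged over layers and heads:

    AssDis_i = mean_{layers, heads} [ KL(P_i ‖ S_i) + KL(S_i ‖ P_i) ]

Training is unsupervised minimax reconstruction: the prior is pulled toward
the (stop-gradient) series association while the series association is
pushed away from the (stop-gradient) prior, both while minimizing
reconstruction error, with early stopping on the validation loss. The
per-step anomaly score is

    score_i = softmax_i(−AssDis) · ‖x_i − x̂_i‖²,

and `s_T` denotes the final-step score. A fixed threshold τ is calibrated
once as the 95th percentile of the training `s_T` distribution and never
recalibrated. **Anomaly-detected AKI** requires a strictly rising final
creatinine (c_T > c_{T−1}) *and* s_T ≥ τ.

**Evaluation.** Score comparisons across KDIGO categories (Mann–Whitney),
AUROC for near-term KRT/mortality on creatinine-rising windows, accuracy/F1
for four decision strategies (anomaly alone, stage 1, stage ≥ 2, anomaly ∧
stage ≥ 2), event-capture decomposition among outcome-positive windows,
risk-stratum odds ratios from the anomaly × stage ≥ 2 cross-classification,
sensitivity analyses (complete-case, alternative threshold percentiles,
shorter effective windows), and representative-example selection.

**Synthetic cohort.** A seeded generator produces admissions with distinct
trajectory regimes (stable, monotonic rise, fluctuating, recovery), a
chronically-elevated-baseline subgroup, ~10% missing lab days, and
KRT/death outcomes whose daily hazard depends on the trajectory (level,
ratio to baseline while rising, day-over-day jumps) plus a
trajectory-independent component. See `docs/methods.md` for the full model
and its limitations.

The model is implemented in NumPy on a small reverse-mode autodiff engine
(`trajaki.autograd`); no deep-learning framework is required.

## Worked example

```bash
python examples/train_and_score.py
```

prints (seeded, reproducible):

```
400 admissions -> 2299 seven-step windows (exclusions: {'eskd': 6,
  'event_within_24h': 2, 'insufficient_measurements': 6, 'too_short_grid': 0})
trained 8 epochs, final validation loss 0.1506
tau (95th percentile of training s_T): 0.0372
training windows at or above tau: 5.0%
test s_T: median 0.00736, max 0.114
```

Six ESKD admissions and two with an event inside 24 h were excluded, the
remaining 392 admissions yielded 2299 rolling windows, and by construction
5% of training windows sit at or above the calibrated threshold; typical
test windows score two orders of magnitude below the most anomalous ones.
`examples/full_evaluation.py` runs the complete pipeline including a second,
frozen-model "external" cohort and prints AUROC, strategy metrics, and
capture rates; `examples/simulate_cohort.py` and `examples/kidney_rules.py`
demonstrate the generator and the deterministic clinical rules. A thin CLI
(`trajaki simulate|preprocess|train|score|evaluate|run-all`) wraps the same
functions for shell use.

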