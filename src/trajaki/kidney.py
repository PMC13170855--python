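"""Deterministic kidney-function rules.

CKD-EPI 2021 race-free eGFR, KDIGO creatinine-based AKI staging over a
seven-step daily window, and the composite anomaly-detected-AKI decision rule.
All functions are pure and accept scalars or NumPy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "compute_egfr",
    "KdigoStage",
    "kdigo_stage",
    "kdigo_stage_array",
    "DecisionFlags",
    "anomaly_aki_rule",
    "STAGE_NONE",
    "STAGE_1",
    "STAGE_2PLUS",
]

STAGE_NONE = "none"
STAGE_1 = "stage1"
STAGE_2PLUS = "stage2plus"

# KDIGO creatinine criteria (daily-grid operationalization):
ABS_RISE_THRESHOLD = 0.3   # mg/dL within 48 h -> stage 1
RATIO_STAGE1_LOW = 1.5     # 1.5 <= ratio < 2.0 -> stage 1
RATIO_STAGE2 = 2.0         # ratio >= 2.0       -> stage >= 2


def compute_egfr(creatinine, age, sex):
    """Estimated GFR (mL/min/1.73 m^2) by the CKD-EPI 2021 race-free equation.

    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200 * 0.9938^age * (1.012 if female)
    with k = 0.7 (female) / 0.9 (male) and a = -0.241 (female) / -0.302 (male).

    Parameters
    ----------
    creatinine : float or array
        Serum creatinine in mg/dL, must be > 0.
    age : float or array
        Age in years.
    sex : str or array of str
        ``"male"`` or ``"female"``.
    """
    scr = np.asarray(creatinine, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("creatinine must be positive")
    female = np.asarray(sex) == "female"
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.241, -0.302)
    ratio = scr / kappa
    egfr = (
        142.0
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** -1.200
        * 0.9938 ** np.asarray(age, dtype=float)
        * np.where(female, 1.012, 1.0)
    )
    if egfr.ndim == 0:
        return float(egfr)
    return egfr


@dataclass(frozen=True)
class KdigoStage:
    """Staging result for one seven-step window.

    ``baseline_used`` is the within-window minimum creatinine (rolling 7-day
    baseline); ``abs_rise_48h`` is the final value minus the minimum over the
    last three daily steps (48 h = two 24-h steps).
    """

    stage: str
    baseline_used: float
    abs_rise_48h: float
    ratio_to_baseline: float


def kdigo_stage(window_creatinine) -> KdigoStage:
    """Stage one seven-step creatinine window by KDIGO creatinine criteria.

    Stage >= 2: final/baseline ratio >= 2.0. Stage 1: 48-h absolute rise
    >= 0.3 mg/dL, or ratio in [1.5, 2.0). Baseline is the window minimum.
    """
    c = np.asarray(window_creatinine, dtype=float)
    if c.shape != (7,):
        raise ValueError("expected a seven-step creatinine window")
    baseline = float(c.min())
    c_last = float(c[-1])
    abs_rise = c_last - float(c[-3:].min())
    ratio = c_last / baseline
    if ratio >= RATIO_STAGE2:
        stage = STAGE_2PLUS
    elif abs_rise >= ABS_RISE_THRESHOLD or ratio >= RATIO_STAGE1_LOW:
        stage = STAGE_1
    else:
        stage = STAGE_NONE
    return KdigoStage(stage, baseline, abs_rise, ratio)


def kdigo_stage_array(creatinine_windows: np.ndarray) -> np.ndarray:
    """Vectorized staging of an (n, 7) array; returns an array of stage labels."""
    c = np.asarray(creatinine_windows, dtype=float)
    baseline = c.min(axis=1)
    c_last = c[:, -1]
    abs_rise = c_last - c[:, -3:].min(axis=1)
    ratio = c_last / baseline
    stages = np.full(c.shape[0], STAGE_NONE, dtype=object)
    stages[(abs_rise >= ABS_RISE_THRESHOLD) | (ratio >= RATIO_STAGE1_LOW)] = STAGE_1
    stages[ratio >= RATIO_STAGE2] = STAGE_2PLUS
    return stages


@dataclass(frozen=True)
class DecisionFlags:
    """Composite anomaly-detected-AKI decision for one window."""

    creatinine_rising: bool
    anomaly_positive: bool
    anomaly_aki: bool


def anomaly_aki_rule(c_prev: float, c_last: float, s_last: float, tau: float) -> DecisionFlags:
    """Anomaly-detected AKI: final-step creatinine strictly rising AND s_T >= tau.

    The rise test is strict (equal values do not count); the score test is
    inclusive (a score exactly at the threshold is positive).
    """
    for name, v in (("c_prev", c_prev), ("c_last", c_last), ("s_last", s_last), ("tau", tau)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    rising = c_last > c_prev
    positive = s_last >= tau
    return DecisionFlags(rising, positive, rising and positive)
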