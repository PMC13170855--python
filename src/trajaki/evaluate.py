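"""Window-level evaluation of the anomaly signal against KDIGO staging.

Score comparisons across AKI stages (Mann-Whitney), AUROC for near-term
KRT/mortality on creatinine-rising windows, accuracy/F1 for four decision
strategies, event-capture decomposition, risk-stratified odds ratios,
sensitivity analyses (complete-case, alternative threshold percentiles,
shorter effective windows), and representative-example selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .kidney import STAGE_1, STAGE_2PLUS, STAGE_NONE, kdigo_stage_array
from .model import AnomalyTransformer, calibrate_threshold
from .preprocess import HORIZONS_H, WINDOW_LEN

logger = logging.getLogger(__name__)

__all__ = [
    "StrategyPrediction",
    "STRATEGIES",
    "STRATA",
    "annotate_windows",
    "compare_scores_by_stage",
    "auroc_by_horizon",
    "classification_metrics",
    "classify_and_score",
    "capture_decomposition",
    "stratum_odds_ratios",
    "sensitivity_suite",
    "select_examples",
    "evaluate_dataset",
]

STRATEGIES = ("anomaly_alone", "aki_stage1", "aki_stage2plus", "anomaly_and_stage2plus")
STRATA = ("anomaly-/stage2-", "anomaly+/stage2-", "anomaly-/stage2+", "anomaly+/stage2+")
OUTCOMES = ("krt", "death")


@dataclass(frozen=True)
class StrategyPrediction:
    strategy: str
    prediction: np.ndarray  # bool per window


def annotate_windows(frame: pd.DataFrame, s_last: np.ndarray, tau: float) -> pd.DataFrame:
    """Append score, KDIGO stage, and rule flags to a windows table.

    Adds: s_last, stage, creatinine_rising (strict), anomaly_positive
    (s_last >= tau, inclusive), anomaly_aki (conjunction), stage2plus, stage1.
    """
    out = frame.copy()
    creat = out[[f"creat_{s}" for s in range(WINDOW_LEN)]].to_numpy()
    out["s_last"] = np.asarray(s_last, dtype=float)
    out["stage"] = kdigo_stage_array(creat)
    out["creatinine_rising"] = out["c_last"].to_numpy() > out["c_prev"].to_numpy()
    out["anomaly_positive"] = out["s_last"].to_numpy() >= tau
    out["anomaly_aki"] = out["creatinine_rising"] & out["anomaly_positive"]
    out["stage2plus"] = out["stage"] == STAGE_2PLUS
    out["stage1"] = out["stage"] == STAGE_1
    return out


def _mannwhitney(a, b):
    """Two-sided Mann-Whitney U; exact for small tie-free samples."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    small = len(a) <= 20 and len(b) <= 20
    method = "exact" if small and len(np.unique(np.r_[a, b])) == len(a) + len(b) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_scores_by_stage(annotated: pd.DataFrame, rising_only: bool = True) -> dict:
    """Median/IQR of s_last per KDIGO category plus pairwise Mann-Whitney tests.

    Restricted to creatinine-rising windows by default, matching the subset on
    which the composite rule operates.
    """
    df = annotated[annotated["creatinine_rising"]] if rising_only else annotated
    groups = {}
    for stage in (STAGE_NONE, STAGE_1, STAGE_2PLUS):
        s = df.loc[df["stage"] == stage, "s_last"].to_numpy()
        groups[stage] = {
            "n": int(s.size),
            "median": float(np.median(s)) if s.size else None,
            "iqr": [float(np.percentile(s, 25)), float(np.percentile(s, 75))] if s.size else None,
            "_scores": s,
        }
    tests = {}
    for a, b in ((STAGE_NONE, STAGE_1), (STAGE_1, STAGE_2PLUS), (STAGE_NONE, STAGE_2PLUS)):
        sa, sb = groups[a]["_scores"], groups[b]["_scores"]
        if sa.size == 0 or sb.size == 0:
            logger.info("stage comparison %s vs %s omitted: empty group", a, b)
            continue
        u, p = _mannwhitney(sa, sb)
        tests[f"{a}_vs_{b}"] = {"U": u, "p": p}
    for g in groups.values():
        g.pop("_scores")
    return {"groups": groups, "tests": tests}


def auroc_by_horizon(annotated: pd.DataFrame, rising_only: bool = True) -> dict:
    """AUROC of s_last for each outcome x horizon on the rising subset.

    Equivalent to the tie-corrected Mann-Whitney U statistic normalized by
    n1*n0. Degenerate subsets (single class) yield None.
    """
    df = annotated[annotated["creatinine_rising"]] if rising_only else annotated
    out: dict = {}
    for outcome in OUTCOMES:
        out[outcome] = {}
        for h in HORIZONS_H:
            y = df[f"{outcome}_within_{h}"].to_numpy(dtype=bool)
            if y.all() or not y.any():
                logger.info("AUROC undefined for %s at %dh (degenerate labels)", outcome, h)
                out[outcome][h] = None
                continue
            out[outcome][h] = float(roc_auc_score(y, df["s_last"].to_numpy()))
    return out


def classification_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Accuracy, F1, precision, recall from a binary prediction.

    Conventions: precision/recall/F1 are 0 when their denominator is 0.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    acc = (tp + tn) / max(1, len(pred))
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return {"accuracy": acc, "f1": f1, "precision": prec, "recall": rec,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn}


def strategy_predictions(annotated: pd.DataFrame) -> list[StrategyPrediction]:
    """The four decision strategies evaluated on all windows."""
    return [
        StrategyPrediction("anomaly_alone", annotated["anomaly_aki"].to_numpy()),
        StrategyPrediction("aki_stage1", annotated["stage1"].to_numpy()),
        StrategyPrediction("aki_stage2plus", annotated["stage2plus"].to_numpy()),
        StrategyPrediction("anomaly_and_stage2plus",
                           (annotated["anomaly_aki"] & annotated["stage2plus"]).to_numpy()),
    ]


def classify_and_score(annotated: pd.DataFrame) -> dict:
    """Accuracy/F1 per strategy, outcome, horizon, on the entire window set."""
    preds = strategy_predictions(annotated)
    out: dict = {}
    for outcome in OUTCOMES:
        out[outcome] = {}
        for h in HORIZONS_H:
            truth = annotated[f"{outcome}_within_{h}"].to_numpy(dtype=bool)
            out[outcome][h] = {p.strategy: classification_metrics(p.prediction, truth)
                               for p in preds}
    return out


def capture_decomposition(annotated: pd.DataFrame) -> dict:
    """Event-capture rates among outcome-positive windows.

    For each outcome x horizon and for both subsets (all windows, rising
    windows): the percentage of outcome-positive windows flagged by anomaly
    detection, by KDIGO stage >= 2, by either, and the mutually exclusive
    anomaly-only / stage2-only shares. These are window-level rule-positivity
    rates among outcome-positive windows, not patient-level sensitivity.
    """
    out: dict = {}
    for subset_name, df in (("all", annotated),
                            ("creatinine_rising", annotated[annotated["creatinine_rising"]])):
        out[subset_name] = {}
        anom = df["anomaly_aki"].to_numpy(dtype=bool)
        stg2 = df["stage2plus"].to_numpy(dtype=bool)
        for outcome in OUTCOMES:
            out[subset_name][outcome] = {}
            for h in HORIZONS_H:
                pos = df[f"{outcome}_within_{h}"].to_numpy(dtype=bool)
                n = int(pos.sum())
                if n == 0:
                    out[subset_name][outcome][h] = {"denominator": 0}
                    continue
                a, s = anom[pos], stg2[pos]
                pct = lambda m: float(100.0 * m.sum() / n)
                out[subset_name][outcome][h] = {
                    "denominator": n,
                    "anomaly_captured": pct(a),
                    "stage2_captured": pct(s),
                    "either_captured": pct(a | s),
                    "anomaly_only": pct(a & ~s),
                    "stage2_only": pct(~a & s),
                    "both": pct(a & s),
                }
    return out


def _stratum_index(anom: np.ndarray, stg2: np.ndarray) -> np.ndarray:
    return np.asarray(anom, bool).astype(int) + 2 * np.asarray(stg2, bool).astype(int)


def stratum_odds_ratios(annotated: pd.DataFrame, haldane: bool = True) -> dict:
    """Odds ratios for outcome occurrence across the four joint-rule strata.

    Strata cross-classify anomaly detection and KDIGO stage >= 2 at the final
    step; anomaly-/stage2- is the reference (OR = 1). Each OR equals the 2x2
    contingency cross-product against the reference stratum (identical to the
    saturated logistic model) with Wald 95% CIs on the log scale; zero cells
    get the Haldane-Anscombe 0.5 correction, flagged in the output.
    """
    idx = _stratum_index(annotated["anomaly_aki"], annotated["stage2plus"])
    out: dict = {}
    for outcome in OUTCOMES:
        out[outcome] = {}
        for h in HORIZONS_H:
            y = annotated[f"{outcome}_within_{h}"].to_numpy(dtype=bool)
            e0 = int(y[idx == 0].sum())
            n0 = int((idx == 0).sum()) - e0  # non-events in reference
            cells = {}
            for k, name in enumerate(STRATA):
                ev = int(y[idx == k].sum())
                ne = int((idx == k).sum()) - ev
                total = ev + ne
                cell = {"n": total, "events": ev,
                        "event_rate": ev / total if total else None}
                if total == 0:
                    cell.update({"or": None, "ci": None, "note": "empty stratum"})
                elif k == 0:
                    cell.update({"or": 1.0, "ci": [1.0, 1.0]})
                else:
                    a, b, c, d = ev, ne, e0, n0
                    corrected = 0 in (a, b, c, d)
                    if corrected and haldane:
                        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
                    if 0 in (a, b, c, d):
                        cell.update({"or": None, "ci": None, "note": "zero cell"})
                    else:
                        orr = (a * d) / (b * c)
                        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
                        lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
                        cell.update({"or": float(orr), "ci": [float(lo), float(hi)],
                                     "haldane_corrected": corrected})
                cells[name] = cell
            out[outcome][h] = cells
    return out


# ---------------------------------------------------------------------------
# sensitivity analyses

def shorten_windows(values: np.ndarray, effective_len: int) -> np.ndarray:
    """Keep only the last `effective_len` steps, left-padding by repetition.

    Emulates shorter observation histories: the earliest retained step is
    repeated (without additional perturbation) to fill the fixed seven-step
    format.
    """
    if not 2 <= effective_len <= WINDOW_LEN:
        raise ValueError("effective_len must be in [2, 7]")
    tail = values[:, WINDOW_LEN - effective_len:, :]
    pad = np.repeat(tail[:, :1, :], WINDOW_LEN - effective_len, axis=1)
    return np.concatenate([pad, tail], axis=1)


def sensitivity_suite(model: AnomalyTransformer, annotated: pd.DataFrame,
                      values: np.ndarray, train_s_last: np.ndarray,
                      alt_percentiles=(90.0, 97.5, 99.0),
                      effective_lengths=(2, 3, 4, 5, 6)) -> dict:
    """Robustness checks around the primary analysis.

    (a) complete-case: AUROC recomputed on windows from admissions without
        interpolated days;
    (b) alternative threshold percentiles (upper tails 10%/2.5%/1%):
        accuracy/F1/precision/recall per outcome and horizon;
    (c) shorter effective input windows (2-6 days) rescored with the frozen
        model: AUROC per outcome and horizon.
    """
    report: dict = {}

    cc = annotated[annotated["complete_case"]]
    if len(cc) == 0:
        logger.info("complete-case sensitivity skipped: empty subset")
        report["complete_case"] = None
    else:
        report["complete_case"] = {"n_windows": int(len(cc)),
                                   "auroc": auroc_by_horizon(cc)}

    report["alt_thresholds"] = {}
    for q in alt_percentiles:
        thr = calibrate_threshold(train_s_last, q=q)
        alt = annotated.copy()
        alt["anomaly_positive"] = alt["s_last"] >= thr.tau
        alt["anomaly_aki"] = alt["creatinine_rising"] & alt["anomaly_positive"]
        metrics = {}
        for outcome in OUTCOMES:
            metrics[outcome] = {}
            for h in HORIZONS_H:
                truth = alt[f"{outcome}_within_{h}"].to_numpy(dtype=bool)
                metrics[outcome][h] = classification_metrics(
                    alt["anomaly_aki"].to_numpy(), truth)
        report["alt_thresholds"][q] = {"tau": thr.tau, "metrics": metrics}

    report["window_length"] = {}
    for L in effective_lengths:
        short = shorten_windows(values, L)
        s_last = model.score(short).s_last
        alt = annotated.copy()
        alt["s_last"] = s_last
        report["window_length"][L] = auroc_by_horizon(alt)
    return report


def select_examples(annotated: pd.DataFrame, horizon: int = 48) -> pd.DataFrame:
    """Four representative windows from the stage2+ x anomaly cross-classification.

    Cells follow the illustrative case set: anomaly-detected cells are paired
    with KRT within `horizon` hours and take the highest s_last; undetected
    cells are paired with no near-term KRT and take the lowest s_last. Empty
    cells are dropped with a logged notice; the KRT pairing is relaxed before
    a cell is dropped.
    """
    krt_col = f"krt_within_{horizon}"
    picks = []
    cells = [
        (True, True, True), (False, True, True),
        (True, False, False), (False, False, False),
    ]
    for stage2, anom, krt in cells:
        sub = annotated[(annotated["stage2plus"] == stage2)
                        & (annotated["anomaly_aki"] == anom)]
        matched = sub[sub[krt_col] == krt]
        if len(matched) == 0:
            logger.info("exemplar cell stage2=%s anomaly=%s: no window with %s=%s; relaxing",
                        stage2, anom, krt_col, krt)
            matched = sub
        if len(matched) == 0:
            logger.info("exemplar cell stage2=%s anomaly=%s empty; skipped", stage2, anom)
            continue
        row = matched.loc[matched["s_last"].idxmax() if anom else matched["s_last"].idxmin()]
        picks.append(row)
    return pd.DataFrame(picks).reset_index(drop=True)


def evaluate_dataset(annotated: pd.DataFrame) -> dict:
    """The full per-dataset report (scores, AUROC, strategies, capture, ORs)."""
    return {
        "n_windows": int(len(annotated)),
        "score_by_stage": compare_scores_by_stage(annotated),
        "auroc": auroc_by_horizon(annotated),
        "strategies": classify_and_score(annotated),
        "capture": capture_decomposition(annotated),
        "odds_ratios": stratum_odds_ratios(annotated),
    }
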