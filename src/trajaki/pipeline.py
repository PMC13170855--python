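"""End-to-end orchestration: generate -> preprocess -> train -> calibrate ->
score -> evaluate, as reproducible, configured, logged runs.

An optional second cohort plays the external-validation role: it is scored
with the frozen model, frozen normalization statistics, and the frozen
threshold, never refitted or recalibrated.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import annotate_windows, evaluate_dataset, select_examples, sensitivity_suite
from .model import AnomalyTransformer, ModelConfig, calibrate_threshold
from .preprocess import preprocess_cohort, split_dataset, windows_to_frame, window_values_array
from .synthetic import CohortConfig, generate_cohort, write_cohort_csv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_experiment", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration for one full experiment run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    external_cohort: Optional[CohortConfig] = None
    split_fractions: tuple = (0.80, 0.05, 0.15)
    threshold_q: float = 95.0
    preprocess_seed: int = 100
    split_seed: int = 200
    output_dir: str = "trajaki_run"
    run_sensitivity: bool = True

    def validate(self):
        if not 0 < self.threshold_q < 100:
            raise ValueError("threshold_q must be in (0, 100)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        self.cohort.validate()
        self.model.validate()
        if self.external_cohort is not None:
            self.external_cohort.validate()


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file of nested sections."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "cohort" in kwargs:
        kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
    if "model" in kwargs:
        kwargs["model"] = ModelConfig(**kwargs["model"])
    if kwargs.get("external_cohort"):
        kwargs["external_cohort"] = CohortConfig(**kwargs["external_cohort"])
    if "split_fractions" in kwargs:
        kwargs["split_fractions"] = tuple(kwargs["split_fractions"])
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _prepare_dataset(cohort_config: CohortConfig, preprocess_seed: int, out_dir: Path,
                     tag: str):
    cohort = generate_cohort(cohort_config)
    write_cohort_csv(cohort, out_dir / f"{tag}_admissions.csv", out_dir / f"{tag}_labs.csv")
    windows, counts = preprocess_cohort(cohort, seed=preprocess_seed)
    logger.info("%s: %d admissions -> %d windows (exclusions: %s)",
                tag, len(cohort), len(windows), counts)
    frame = windows_to_frame(windows)
    values = window_values_array(windows)
    return frame, values, counts


def run_experiment(config: RunConfig) -> dict:
    """Execute the full chain; returns the metrics report (also written to disk).

    Artifacts under `config.output_dir`: cohort CSVs, windows tables, split
    assignment, anomaly-score CSVs, the model checkpoint, the JSON report,
    and a manifest recording the config hash, seeds, and software versions.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    frame, values, counts = _prepare_dataset(config.cohort, config.preprocess_seed,
                                             out, "internal")
    parts = split_dataset(len(frame), config.split_fractions, seed=config.split_seed)
    frame["partition"] = parts
    frame[["window_id", "partition"]].to_csv(out / "split_assignment.csv", index=False)

    tr, va, te = (values[parts == p] for p in ("train", "validation", "test"))
    if len(tr) == 0 or len(va) == 0:
        raise RuntimeError("train/validation partitions are empty; increase cohort size")
    model = AnomalyTransformer(config.model)
    model.fit(tr, va)

    train_s_last = model.score(tr).s_last
    threshold = calibrate_threshold(train_s_last, q=config.threshold_q)
    model.threshold = threshold
    model.save(out / "checkpoint.npz")

    report: dict = {
        "threshold": {"tau": threshold.tau, "q": threshold.q},
        "exclusions": {"internal": counts},
        "training": {"epochs_run": len(model.history["val_loss"]),
                     "best_val_loss": min(model.history["val_loss"])},
        "datasets": {},
    }

    test_frame = frame[frame["partition"] == "test"].reset_index(drop=True)
    sv = model.score(te)
    annotated = annotate_windows(test_frame, sv.s_last, threshold.tau)
    annotated.to_csv(out / "internal_test_windows_scored.csv", index=False)
    report["datasets"]["internal_test"] = evaluate_dataset(annotated)
    select_examples(annotated).to_csv(out / "exemplars_internal.csv", index=False)
    if config.run_sensitivity:
        report["datasets"]["internal_test"]["sensitivity"] = sensitivity_suite(
            model, annotated, te, train_s_last)

    if config.external_cohort is not None:
        # frozen model, frozen normalization, frozen threshold
        ext_frame, ext_values, ext_counts = _prepare_dataset(
            config.external_cohort, config.preprocess_seed + 1, out, "external")
        report["exclusions"]["external"] = ext_counts
        ext_scores = model.score(ext_values)
        ext_annot = annotate_windows(ext_frame, ext_scores.s_last, threshold.tau)
        ext_annot.to_csv(out / "external_windows_scored.csv", index=False)
        report["datasets"]["external"] = evaluate_dataset(ext_annot)
        if config.run_sensitivity:
            report["datasets"]["external"]["sensitivity"] = sensitivity_suite(
                model, ext_annot, ext_values, train_s_last)

    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "config": asdict(config),
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
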