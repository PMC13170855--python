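"""Shared fixtures.

The session-scoped ``trained_pipeline`` fixture runs the reference synthetic
study once — generate, preprocess, split, train (smoke scale), calibrate,
score, annotate — and is reused by the model-level and acceptance tests so
the expensive training happens a single time.
"""

from __future__ import annotations

import numpy as np
import pytest

from trajaki import (
    AnomalyTransformer,
    CohortConfig,
    ModelConfig,
    calibrate_threshold,
    generate_cohort,
)
from trajaki.evaluate import annotate_windows
from trajaki.preprocess import (
    preprocess_cohort,
    split_dataset,
    window_values_array,
    windows_to_frame,
)

# Reference study conditions: frozen seeds, smoke-scale training.
COHORT_SEED = 1
PREPROCESS_SEED = 101
SPLIT_SEED = 201
MODEL_SEED = 1
SMOKE_EPOCHS = 25


@pytest.fixture(scope="session")
def study_cohort():
    return generate_cohort(CohortConfig(n_admissions=2000, seed=COHORT_SEED))


@pytest.fixture(scope="session")
def study_windows(study_cohort):
    windows, counts = preprocess_cohort(study_cohort, seed=PREPROCESS_SEED)
    return windows, counts


@pytest.fixture(scope="session")
def trained_pipeline(study_windows):
    windows, _ = study_windows
    frame = windows_to_frame(windows)
    values = window_values_array(windows)
    parts = split_dataset(len(frame), seed=SPLIT_SEED)
    tr = values[parts == "train"]
    va = values[parts == "validation"]
    te = values[parts == "test"]
    model = AnomalyTransformer(ModelConfig(seed=MODEL_SEED, max_epochs=SMOKE_EPOCHS))
    model.fit(tr, va)
    train_s_last = model.score(tr).s_last
    threshold = calibrate_threshold(train_s_last, q=95.0)
    model.threshold = threshold
    test_frame = frame[parts == "test"].reset_index(drop=True)
    ann_test = annotate_windows(test_frame, model.score(te).s_last, threshold.tau)
    ann_all = annotate_windows(frame, model.score(values).s_last, threshold.tau)
    return {
        "frame": frame,
        "values": values,
        "parts": parts,
        "model": model,
        "threshold": threshold,
        "train_s_last": train_s_last,
        "ann_test": ann_test,
        "ann_all": ann_all,
        "test_values": te,
    }


def _fit_and_annotate(frame, values, parts, model_seed):
    tr = values[parts == "train"]
    va = values[parts == "validation"]
    te = values[parts == "test"]
    model = AnomalyTransformer(ModelConfig(seed=model_seed, max_epochs=SMOKE_EPOCHS))
    model.fit(tr, va)
    train_s_last = model.score(tr).s_last
    threshold = calibrate_threshold(train_s_last, q=95.0)
    model.threshold = threshold
    test_frame = frame[parts == "test"].reset_index(drop=True)
    return {
        "model": model,
        "threshold": threshold,
        "train_s_last": train_s_last,
        "ann_test": annotate_windows(test_frame, model.score(te).s_last, threshold.tau),
        "ann_all": annotate_windows(frame, model.score(values).s_last, threshold.tau),
        "test_values": te,
    }


@pytest.fixture(scope="session")
def model_panel(study_windows, trained_pipeline):
    """Three independently initialized detectors on the same cohort.

    Directional acceptance clauses are stochastic at smoke scale, so they are
    asserted on the panel majority rather than on a single initialization.
    """
    windows, _ = study_windows
    frame = windows_to_frame(windows)
    values = window_values_array(windows)
    parts = split_dataset(len(frame), seed=SPLIT_SEED)
    panel = []
    for seed in (0, 1, 2):
        if seed == MODEL_SEED:
            panel.append(trained_pipeline)  # reuse the already-trained model
        else:
            panel.append(_fit_and_annotate(frame, values, parts, seed))
    return panel


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
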