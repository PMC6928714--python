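"""Shared fixtures: a study-scale synthetic cohort (150 PwP + 150 controls)
with its trained severity model and per-subject results, built once per
session, plus a small quick cohort for unit tests."""

from __future__ import annotations

import warnings

import pandas as pd
import pytest

from pkg_ldct.ldct_pipeline import collect_window_samples, run_cohort
from pkg_ldct.severity_model import SplitSpec, build_training_set, train
from pkg_ldct.synthetic_data import SimulationConfig, simulate_cohort

STUDY_SEED = 7
SPLIT_SEED = 3


@pytest.fixture(scope="session")
def study_cohort():
    config = SimulationConfig(n_pwp=150, n_controls=150, seed=STUDY_SEED)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def study_model(study_cohort):
    recordings, _ = study_cohort
    samples = collect_window_samples(recordings)
    labeled = build_training_set(samples)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return train(labeled, split=SplitSpec(seed=SPLIT_SEED))


@pytest.fixture(scope="session")
def study_results(study_cohort, study_model) -> pd.DataFrame:
    recordings, _ = study_cohort
    return run_cohort(recordings, study_model)


@pytest.fixture(scope="session")
def study_truth(study_cohort) -> pd.DataFrame:
    _, truths = study_cohort
    return pd.DataFrame([t.__dict__ for t in truths])


@pytest.fixture(scope="session")
def quick_cohort():
    """Small cohort for structural unit tests (3 PwP + 2 controls, 3 days)."""
    config = SimulationConfig(n_pwp=3, n_controls=2, n_days=3, seed=42)
    return simulate_cohort(config)
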