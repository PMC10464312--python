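"""Shared fixtures: small synthetic cohorts and generator parameters."""

import numpy as np
import pandas as pd
import pytest

import medhaz as mh
from medhaz.decompose import DecompositionConfig


@pytest.fixture(scope="session")
def binary_params():
    """Default binary-contrast generator parameters, men only (the
    scaled-down study condition used throughout the suite)."""
    p = mh.default_params(n=5000)
    p.sex_probs = {"men": 1.0}
    return p


@pytest.fixture(scope="session")
def binary_cohort(binary_params):
    return mh.generate_cohort(binary_params, seed=314)


@pytest.fixture(scope="session")
def binary_config():
    return DecompositionConfig(exposure_levels=["white", "black"])


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny two-sex cohort (n=1200) for structural tests."""
    p = mh.default_params(n=1200)
    return mh.generate_cohort(p, seed=99)


def toy_cohort_frame(n=3):
    """Minimal hand-written valid cohort table."""
    rows = []
    for i in range(n):
        rows.append(
            {
                "subject_id": i,
                "race_ethnicity": ["white", "black", "other"][i % 3],
                "sex": "men" if i % 2 == 0 else "women",
                "age_at_survey": 40.0 + i,
                "education": "low",
                "married": 1,
                "survey_year": 2000 + i,
                "alcohol_category": "cat_i",
                "smoking_category": "never",
                "bmi_category": "normal",
                "activity_category": "active",
                "entry_age": 40.0 + i,
                "exit_age": 50.0 + i,
                "event": i % 2,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def toy_frame():
    return toy_cohort_frame()


def random_survival_design(rng, n_rows, p=2, weighted=True):
    """Random small survival design for oracle fuzzing."""
    entry = rng.uniform(0, 5, n_rows)
    exit_ = entry + rng.uniform(0.1, 5, n_rows)
    event = rng.integers(0, 2, n_rows)
    if event.sum() == 0:
        event[rng.integers(0, n_rows)] = 1
    Z = rng.normal(size=(n_rows, p))
    w = rng.uniform(0.2, 3.0, n_rows) if weighted else None
    return mh.SurvivalDesign(
        entry=entry,
        exit=exit_,
        event=event,
        Z=Z,
        names=[f"z{j}" for j in range(p)],
        weights=w,
        cluster=np.arange(n_rows),
    )
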