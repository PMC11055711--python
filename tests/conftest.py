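import numpy as np
import pandas as pd
import pytest

from cogpheno import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_controls=60, n_patients=200, seed=7)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def null_sim():
    """Cohort with zero injected effects: every patient is HC-like."""
    cfg = CohortConfig(
        n_controls=96,
        n_patients=2000,
        seed=11,
        group_mix={"preserved": 1.0},
        domain_effects={"preserved": {}},
        followup_drift=0.0,
        retention=1.0,
    )
    return simulate_cohort(cfg)


def make_cohort(demo_rows, score_rows, mri_rows=None):
    """Assemble a Cohort from plain dict rows (test helper)."""
    from cogpheno.cohort import DEMO_COLUMNS, Cohort

    demo = pd.DataFrame(demo_rows)
    fill = {"retained": True, "ms_type": "none"}
    for col in DEMO_COLUMNS:
        if col not in demo.columns:
            demo[col] = fill.get(col, np.nan)
    demo = demo[DEMO_COLUMNS]
    scores = pd.DataFrame(score_rows, columns=["subject_id", "timepoint", "subscore", "value"])
    mri = pd.DataFrame(mri_rows) if mri_rows else pd.DataFrame(columns=["subject_id"])
    return Cohort(demographics=demo, scores=scores, mri=mri)
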