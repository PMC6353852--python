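import numpy as np
import pandas as pd
import pytest

from bayemo.experiment import (
    ConditionMapping,
    ErpConfig,
    ExperimentConfig,
    LikertConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_experiment() -> ExperimentConfig:
    """Cheap 3-subject, 3-set design for fast pipeline tests."""
    return ExperimentConfig(n_subjects=3, n_sets=3)


@pytest.fixture
def quiet_erp() -> ErpConfig:
    """Deterministic forward model: no noise, no latency jitter, no offsets."""
    return ErpConfig(
        p300_latency_sd_ms=0.0,
        noise_sd_uv=0.0,
        subject_sd_uv=0.0,
        subject_condition_sd_uv=0.0,
    )


def balanced_long_table(rng: np.random.Generator, n_subjects=6, la=("A", "B"),
                        lb=("X", "Y"), effect=None) -> pd.DataFrame:
    """Random balanced within-subject table, optionally with added cell effects."""
    rows = []
    for s in range(1, n_subjects + 1):
        subj = rng.normal(0, 1)
        for a in la:
            for b in lb:
                value = subj + rng.normal(0, 1)
                if effect is not None:
                    value += effect(a, b)
                rows.append((s, a, b, value))
    return pd.DataFrame(rows, columns=["subject_id", "familiarity", "congruity", "value"])
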