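"""Shared fixtures: small synthetic problems generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from megconn.nbs import SubjectTable
from megconn.synth import SimulationConfig


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def small_config() -> SimulationConfig:
    """A 10-subject, 12-ROI cohort, cheap enough for per-test generation."""
    return SimulationConfig(
        n_group_a=6,
        n_group_b=4,
        n_rois=12,
        n_sensors=24,
        sampling_rate=250.0,
        trial_length=2.0,
        n_trials=6,
        n_trials_margin=2,
        planted_links=[(0, 5), (0, 7), (1, 5), (1, 7)],
        seed=7,
    )


@pytest.fixture
def toy_table() -> SubjectTable:
    """Eight subjects, 5/3 split, fixed ages and scores."""
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(8)],
            "group": ["Val/Val"] * 5 + ["Val/Met"] * 3,
            "age": [61.0, 64.5, 70.0, 73.5, 78.0, 62.5, 69.0, 76.5],
            "education": [10.0, 12.0, 14.0, 9.0, 16.0, 11.0, 13.0, 8.0],
            "score_fds": [7.0, 8.5, 6.0, 9.0, 8.0, 5.5, 6.5, 7.5],
        }
    )
    return SubjectTable(frame=frame)
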