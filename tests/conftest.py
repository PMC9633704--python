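"""Shared fixtures: simulated cohorts at two scales.

``planted_cohort_measures`` is the full study-scale recovery experiment
(20 base seeds, 12/11/18/18 subjects across the four ordered conditions)
and is session-scoped because it takes several minutes; cheaper tests
use ``small_cohort`` / ``mini_contrast`` instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fcdyn.io import PipelineConfig
from fcdyn.pipeline import compute_subject_measures
from fcdyn.synth import CohortSpec, SimulationConfig, generate_cohort

CONDITIONS = ("UWS", "MCS", "SED", "CON")


@pytest.fixture(scope="session")
def small_cohort():
    """One base seed, 4 conditions x 4 subjects, default single-subject
    geometry (T=145, R=30)."""
    spec = CohortSpec(n_subjects_per_condition=4, base_seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def mini_contrast():
    """Two-seed, extreme-conditions-only cohorts (6 UWS vs 6 CON each)
    with their per-subject measures, for cheap directional checks."""
    cfg = PipelineConfig(tdsm_kinds=("exp_slow",))
    frames = []
    for seed in (3, 4):
        spec = CohortSpec(conditions=("UWS", "CON"),
                          n_subjects_per_condition=6, base_seed=seed)
        for subj in generate_cohort(spec):
            vals = compute_subject_measures(subj.timeseries, subj.connectome,
                                            cfg)
            vals.update(condition=subj.condition, seed=seed)
            frames.append(vals)
    return pd.DataFrame(frames)


@pytest.fixture(scope="session")
def planted_cohort_measures():
    """Per-subject measures for 20 planted cohorts at the study's group
    sizes (UWS=12, MCS=11, SED=18, CON=18), least to most aware."""
    cfg = PipelineConfig(tdsm_kinds=("exp_slow",))
    rows = []
    for seed in range(20):
        spec = CohortSpec(base_seed=seed)
        for subj in generate_cohort(spec):
            vals = compute_subject_measures(subj.timeseries, subj.connectome,
                                            cfg)
            vals.update(condition=subj.condition, seed=seed)
            rows.append(vals)
    return pd.DataFrame(rows)


def extreme_gap(df: pd.DataFrame, measure: str) -> pd.Series:
    """Per-seed difference of condition means: least aware (UWS) minus
    most aware (CON)."""
    g = df.groupby(["seed", "condition"])[measure].mean().reset_index()
    p = g.pivot(index="seed", columns="condition", values=measure)
    return p["UWS"] - p["CON"]
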