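"""Shared fixtures: cohorts, schemas, and smoke-scale training configs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from psyprog.config import (ArchitectureConfig, CohortConfig, EffectParams)
from psyprog.cohort import apply_attrition_funnel, generate_cohort, simulate_cohort
from psyprog.preprocess import prepare
from psyprog.schema import default_schema


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def default_cohort():
    """The default study fixture: 446 enrolled, funnel applied, missingness in."""
    return simulate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def smoke_arch():
    """Small, fast architecture used throughout the training-level tests."""
    return ArchitectureConfig(hidden_panss=8, hidden_psp=4, hidden_cgi=4,
                              fusion_width=24, interaction_width=12,
                              train_epochs=8, train_batch=8,
                              augmentation_multiplier=1, learning_rate=3e-3,
                              seed=0)


def planted_cohort(seed: int, n: int = 600, betas: dict | None = None,
                   gamma: float = 0.0, noise_sd: float = 0.5,
                   coupling: float = 0.0) -> pd.DataFrame:
    """Fully-observed cohort (no attrition) with configurable planted effects."""
    eff = EffectParams(beta0=0.0, betas=betas or {}, gamma=gamma,
                       noise_sd=noise_sd, trajectory_outcome_coupling=coupling)
    cfg = CohortConfig(n_enrolled=n, funnel_targets=(n, n, n, n),
                       effect_params=eff, seed=seed)
    cohort = generate_cohort(cfg)
    for flag in ("completed_phase1", "continued_phase2", "completed_phase2",
                 "panss_complete"):
        cohort[flag] = True
    return cohort


@pytest.fixture(scope="session")
def tiny_tensorset(schema):
    """Encoded tensors for a small fully-observed cohort (40 patients)."""
    cohort = planted_cohort(5, n=40, coupling=1.0)
    return prepare(cohort, schema)
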