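"""Synthetic cohort generator: marginals, funnel, trajectories, missingness."""

from __future__ import annotations

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from psyprog.config import CohortConfig, ConfigError, EffectParams, TrajectoryParams
from psyprog.cohort import (apply_attrition_funnel, generate_cohort,
                            inject_missingness, simulate_cohort,
                            simulate_trajectories, write_cohort)
from psyprog.mini_items import MINI_CATEGORIES, MINI_COLUMNS
from psyprog.schema import ANDREASEN_ITEMS, PANSS_ITEMS

from conftest import planted_cohort


@pytest.fixture(scope="module")
def big_cohort():
    """n = 10,000 draw from the default configuration (no attrition)."""
    cfg = dataclasses.replace(CohortConfig(), n_enrolled=10_000, seed=7)
    return generate_cohort(cfg)


def binom_3sd(p, n):
    return 3 * np.sqrt(p * (1 - p) / n)


class TestMarginalCalibration:
    """Each configured fraction is matched within 3 binomial SDs at n=10,000."""

    @pytest.mark.parametrize("column,expected", [
        ("sex_male", 0.79),
        ("admitted", 0.55),
        ("occupation_status", 0.32),
    ])
    def test_binary_fractions(self, big_cohort, column, expected):
        assert abs(big_cohort[column].mean() - expected) < binom_3sd(expected, 10_000)

    def test_dsm_schizophrenia_fraction(self, big_cohort):
        frac = (big_cohort["dsm_classification"] == "schizophrenia").mean()
        assert abs(frac - 0.67) < binom_3sd(0.67, 10_000)

    def test_age_and_duration_means(self, big_cohort):
        assert abs(big_cohort["age"].mean() - 25.3) < 0.2
        assert abs(big_cohort["episode_duration_months"].mean() - 2.5) < 0.1

    def test_comorbidity_block_marginals(self, big_cohort):
        mini = big_cohort[MINI_COLUMNS].to_numpy()
        any_f = mini.any(axis=1).mean()
        assert abs(any_f - 0.30) < 0.02
        mood_idx = [i - 1 for i, _ in MINI_CATEGORIES["mood"]]
        assert abs(mini[:, mood_idx].any(axis=1).mean() - 0.21) < 0.02
        anx_idx = [i - 1 for i, _ in MINI_CATEGORIES["anxiety"]]
        assert abs(mini[:, anx_idx].any(axis=1).mean() - 0.18) < 0.02
        assert abs(big_cohort["mini_11"].mean() - 0.20) < binom_3sd(0.20, 10_000)


class TestDeterminismAndValidation:
    def test_identical_config_identical_serialized_cohort(self):
        cfg = CohortConfig(n_enrolled=120, funnel_targets=(100, 90, 80, 70), seed=9)
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            write_cohort(simulate_cohort(cfg), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]

    def test_invalid_funnel_ordering_rejected(self):
        with pytest.raises(ConfigError, match="non-increasing"):
            CohortConfig(funnel_targets=(100, 200, 72, 66)).validate()

    def test_funnel_target_exceeding_cohort_rejected(self):
        cfg = CohortConfig(n_enrolled=50, funnel_targets=(40, 30, 20, 10), seed=1)
        cohort = generate_cohort(cfg)
        big = dataclasses.replace(cfg, funnel_targets=(60, 30, 20, 10))
        with pytest.raises(ConfigError, match="exceeds"):
            apply_attrition_funnel(cohort, big)


class TestAttritionFunnel:
    def test_stage_counts_exact(self, default_cohort):
        assert len(default_cohort) == 446
        assert default_cohort["completed_phase1"].sum() == 371
        assert default_cohort["continued_phase2"].sum() == 100
        assert default_cohort["completed_phase2"].sum() == 72
        assert default_cohort["panss_complete"].sum() == 66

    def test_flags_nested(self, default_cohort):
        f = default_cohort
        assert (f["completed_phase2"] <= f["continued_phase2"]).all()
        assert (f["continued_phase2"] <= f["completed_phase1"]).all()
        assert (f["panss_complete"] <= f["completed_phase2"]).all()

    def test_degenerate_funnel_no_attrition(self):
        n = 80
        cfg = CohortConfig(n_enrolled=n, funnel_targets=(n, n, n, n), seed=2)
        out = apply_attrition_funnel(generate_cohort(cfg), cfg)
        for flag in ("completed_phase1", "continued_phase2",
                     "completed_phase2", "panss_complete"):
            assert out[flag].all()


class TestPlantedEffects:
    # two-sided Monte-Carlo oracle on the propensity model at 1e6 draws:
    # beta_1 = -2, eps ~ N(0,1) => P(remit|yes) = 0.1557, P(remit|no) = 0.8447
    ORACLE_GAP = -0.6890

    def test_symmetric_null_gives_half_remission(self):
        cohort = planted_cohort(3, n=10_000, betas={}, gamma=0.0, noise_sd=1.0)
        assert abs(cohort["remission_sr"].mean() - 0.5) < binom_3sd(0.5, 10_000)

    def test_planted_depression_effect_matches_mc_oracle(self):
        cohort = planted_cohort(4, n=5_000, betas={1: -2.0}, gamma=0.0,
                                noise_sd=1.0)
        yes = cohort.loc[cohort["mini_01"] == 1, "remission_sr"].mean()
        no = cohort.loc[cohort["mini_01"] == 0, "remission_sr"].mean()
        assert yes < no
        # item-1 prevalence ~11% => ~550 "yes" patients; 3-SD binomial noise
        tol = 3 * np.sqrt(0.15 * 0.85 / 500) + 3 * np.sqrt(0.15 * 0.85 / 4000)
        assert abs((yes - no) - self.ORACLE_GAP) < tol

    def test_planted_effect_direction_across_seeds(self):
        hits = 0
        for seed in range(10):
            cohort = planted_cohort(seed, n=2_000, betas={2: 1.5}, gamma=0.0,
                                    noise_sd=1.0)
            yes = cohort.loc[cohort["mini_02"] == 1, "remission_sr"].mean()
            no = cohort.loc[cohort["mini_02"] == 0, "remission_sr"].mean()
            hits += yes > no
        assert hits == 10


class TestTrajectories:
    def test_remitters_satisfy_severity_rule_at_final_visit(self):
        cohort = planted_cohort(6, n=300, coupling=1.0)
        crit_cols = [f"panss_{it}_w8" for it in ANDREASEN_ITEMS]
        crit = cohort[crit_cols].to_numpy()
        remit = cohort["remission_sr"].to_numpy().astype(bool)
        assert (crit[remit] <= 3).all()
        assert (crit[~remit] >= 4).any(axis=1).all()

    def test_panss_within_instrument_bounds(self):
        cohort = planted_cohort(7, n=300, coupling=1.0)
        cols = [f"panss_{it}_w{w}" for it in PANSS_ITEMS for w in (0, 2, 3, 5, 6, 8)]
        vals = cohort[cols].to_numpy()
        assert vals.min() >= 1 and vals.max() <= 7

    def test_zero_decay_means_no_drift(self):
        cfg = CohortConfig(
            n_enrolled=1_000, funnel_targets=(1000,) * 4, seed=8,
            effect_params=EffectParams(betas={}, gamma=0.0,
                                       trajectory_outcome_coupling=0.0),
            trajectory_params=TrajectoryParams(decay_scale=0.0, noise_sd=0.3))
        cohort = generate_cohort(cfg)
        base = cohort[[f"panss_{it}_w0" for it in PANSS_ITEMS]].to_numpy()
        final = cohort[[f"panss_{it}_w8" for it in PANSS_ITEMS]].to_numpy()
        drift = (final - base).mean()
        assert abs(drift) < 0.05

    def test_single_patient_wrapper_matches_contract(self):
        cohort = planted_cohort(9, n=5, coupling=1.0)
        row = cohort.iloc[0]
        series = simulate_trajectories(row, CohortConfig(), seed=1)
        assert list(series.index) == [0, 2, 3, 5, 6, 8]
        panss = series[[f"panss_{it}" for it in PANSS_ITEMS]].to_numpy()
        assert panss.min() >= 1 and panss.max() <= 7
        with pytest.raises(ValueError, match="remission_sr"):
            simulate_trajectories(row.drop("remission_sr"), CohortConfig(), 1)


class TestMissingness:
    def test_rate_zero_is_identity(self):
        cfg = CohortConfig(n_enrolled=60, funnel_targets=(50, 40, 30, 20), seed=3,
                           missingness_rates={k: 0.0 for k in
                                              CohortConfig().missingness_rates})
        cohort = generate_cohort(cfg)
        out = inject_missingness(cohort, cfg)
        pd.testing.assert_frame_equal(out, cohort)

    def test_rate_one_saturates_modality(self):
        rates = dict(CohortConfig().missingness_rates)
        rates["swn"] = 1.0
        cfg = CohortConfig(n_enrolled=50, funnel_targets=(40, 30, 20, 10),
                           seed=4, missingness_rates=rates)
        out = inject_missingness(generate_cohort(cfg), cfg)
        swn_cols = [c for c in out.columns if c.startswith("swn_")]
        assert out[swn_cols].isna().all().all()

    def test_intermediate_rate_within_binomial_bound(self):
        rates = {k: 0.0 for k in CohortConfig().missingness_rates}
        rates["swn"] = 0.1
        cfg = CohortConfig(n_enrolled=500, funnel_targets=(400, 300, 200, 100),
                           seed=5, missingness_rates=rates)
        out = inject_missingness(generate_cohort(cfg), cfg)
        swn_cols = [c for c in out.columns if c.startswith("swn_")]
        frac = out[swn_cols].isna().to_numpy().mean()
        assert abs(frac - 0.1) < binom_3sd(0.1, 500 * 20)

    def test_outcome_never_missing(self, default_cohort):
        assert default_cohort["remission_sr"].notna().all()
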