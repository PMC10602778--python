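"""Configuration dataclasses for the cohort simulator, model, and pipeline.

Defaults encode the study conditions of the multicenter first-episode
psychosis sample the simulator emulates: 446 enrolled, 371 phase-1
completers, 72 phase-2 completers, 66 with complete PANSS; 79% male, mean
age 25.3 y, 55% admitted, DSM split 67/32/2 (schizophrenia /
schizophreniform / schizoaffective), mean episode duration 2.5 months, 30%
any psychiatric comorbidity, 20% current suicidality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

from .mini_items import (
    MINI_CATEGORIES,
    N_MINI_ITEMS,
    ITEM_MDE_CURRENT,
    ITEM_MDE_RECURRENT,
    ITEM_MDE_MELANCHOLIC_RECURRENT,
    ITEM_SUICIDALITY_CURRENT,
    ITEM_SUBSTANCE_ABUSE_12M,
)

VISIT_WEEKS = (0, 2, 3, 5, 6, 8)
N_VISITS = len(VISIT_WEEKS)


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class DemographicParams:
    male_fraction: float = 0.79
    age_mean: float = 25.3
    age_sd: float = 5.0          # printed "(0.8)" is implausible as an SD; see docs
    admitted_fraction: float = 0.55
    # schizophrenia / schizophreniform / schizoaffective
    dsm_probs: tuple[float, float, float] = (0.67, 0.315, 0.015)
    episode_duration_mean: float = 2.5   # months
    episode_duration_sd: float = 1.5
    work_school_fraction: float = 0.32
    n_sites: int = 8


def _default_category_rates() -> dict[str, float]:
    # Conditional activation rates given "any comorbidity": calibrated so the
    # marginals match 21% mood, 18% anxiety, 5% substance-use (alcohol +
    # substance pooled), 20% current suicidality at a 30% any-comorbidity gate.
    return {
        "mood": 0.70,
        "suicidality": 2.0 / 3.0,
        "anxiety": 0.60,
        "alcohol": 1.0 / 12.0,
        "substance": 1.0 / 12.0,
        "eating": 0.10,
        "somatoform": 0.10,
        "other": 0.05,
    }


def _default_item_rates() -> dict[int, float]:
    # Conditional P(item = yes | its category active); every active category
    # forces at least one positive item, so these shape within-block spread.
    rates = {i: 0.25 for i in range(1, N_MINI_ITEMS + 1)}
    rates[ITEM_MDE_CURRENT] = 0.55
    rates[ITEM_MDE_RECURRENT] = 0.40
    rates[ITEM_MDE_MELANCHOLIC_RECURRENT] = 0.25
    rates[ITEM_SUICIDALITY_CURRENT] = 1.0   # active suicidality block => current positive
    rates[12] = 0.50
    rates[ITEM_SUBSTANCE_ABUSE_12M] = 0.60
    return rates


@dataclass
class ComorbidityParams:
    """Hierarchical category-activation model for the 48 binary items.

    A Bernoulli(any_rate) gate selects comorbid patients; for them each
    diagnostic category activates independently at ``category_rates`` and
    items within an active category turn positive at ``item_rates`` (with at
    least one item forced positive per active category, and at least one
    category forced per comorbid patient). Non-comorbid patients answer
    "no" on all 48 items.
    """

    any_rate: float = 0.30
    category_rates: dict[str, float] = field(default_factory=_default_category_rates)
    item_rates: dict[int, float] = field(default_factory=_default_item_rates)
    forced_category: str = "mood"


def _default_betas() -> dict[int, float]:
    # Planted per-item effects on the remission propensity, mirroring the
    # direction of the published group-level findings: depressive episodes
    # hurt the remission chance, current suicidality and recent substance
    # abuse carry positive coefficients.
    return {
        ITEM_MDE_CURRENT: -0.8,
        ITEM_MDE_RECURRENT: -0.6,
        ITEM_MDE_MELANCHOLIC_RECURRENT: -0.5,
        ITEM_SUICIDALITY_CURRENT: 0.7,
        ITEM_SUBSTANCE_ABUSE_12M: 0.7,
    }


@dataclass
class EffectParams:
    """Remission propensity: p = sigmoid(b0 + sum_i beta_i x_i + gamma*s + eps),
    with x_i in {-1,+1} for item C_i, s the standardized baseline PANSS total,
    eps ~ N(0, noise_sd)."""

    beta0: float = 0.0
    betas: dict[int, float] = field(default_factory=_default_betas)
    gamma: float = -0.5
    noise_sd: float = 1.0
    # 1.0: symptom trajectories encode the outcome (remitters satisfy the
    # severity rule at the final visit); 0.0: trajectories are outcome-blind.
    trajectory_outcome_coupling: float = 1.0


@dataclass
class TrajectoryParams:
    """Symptom-course model: each dynamic feature relaxes exponentially from
    its baseline toward an endpoint, v(w) = e + (b - e) * exp(-r * w / 8),
    with visit week w, plus bounded observation noise."""

    decay_scale: float = 1.0      # global multiplier on relaxation rates r
    noise_sd: float = 0.3         # raw instrument points
    remit_rate_range: tuple[float, float] = (1.5, 3.0)
    nonremit_rate_range: tuple[float, float] = (0.2, 1.0)


def _default_missingness() -> dict[str, float]:
    return {
        "demographic": 0.05,
        "diagnostic": 0.05,
        "lifestyle": 0.10,
        "somatic": 0.10,
        "treatment": 0.05,
        "cdss": 0.10,
        "swn": 0.15,
        "mini": 0.0,
    }


@dataclass
class CohortConfig:
    n_enrolled: int = 446
    # phase-1 completion, phase-2 continuation, phase-2 completion, complete PANSS
    funnel_targets: tuple[int, int, int, int] = (371, 100, 72, 66)
    demographic_params: DemographicParams = field(default_factory=DemographicParams)
    comorbidity_params: ComorbidityParams = field(default_factory=ComorbidityParams)
    effect_params: EffectParams = field(default_factory=EffectParams)
    trajectory_params: TrajectoryParams = field(default_factory=TrajectoryParams)
    missingness_rates: dict[str, float] = field(default_factory=_default_missingness)
    seed: int = 0

    def validate(self) -> "CohortConfig":
        d = self.demographic_params
        fracs = {
            "male_fraction": d.male_fraction,
            "admitted_fraction": d.admitted_fraction,
            "work_school_fraction": d.work_school_fraction,
            "any_rate": self.comorbidity_params.any_rate,
            **{f"missingness[{k}]": v for k, v in self.missingness_rates.items()},
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(d.dsm_probs) - 1.0) > 1e-9:
            raise ConfigError(f"dsm_probs must sum to 1, got {d.dsm_probs}")
        ft = self.funnel_targets
        if len(ft) != 4:
            raise ConfigError("funnel_targets must have 4 stages")
        if any(b > a for a, b in zip(ft, ft[1:])):
            raise ConfigError(f"funnel_targets must be non-increasing, got {ft}")
        if self.n_enrolled < ft[0]:
            raise ConfigError(
                f"n_enrolled ({self.n_enrolled}) < first funnel target ({ft[0]})"
            )
        if set(self.comorbidity_params.category_rates) != set(MINI_CATEGORIES):
            raise ConfigError("category_rates must cover exactly the MINI categories")
        return self

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class ArchitectureConfig:
    """Network and training hyperparameters.

    Optimizer settings follow the published training procedure: Adam at
    3e-4 with exponential decay (rate 0.9 every 10,000 steps), pretraining
    for 2 epochs at batch 25, training for 50 epochs at batch 2. Layer
    widths are not published for this architecture and default to modest
    values suited to a ~66-patient sample.
    """

    hidden_panss: int = 16
    hidden_psp: int = 16
    hidden_cgi: int = 16
    fusion_width: int = 64
    interaction_width: int = 32
    w_mse: float = 1.0
    w_ce: float = 1.0
    learning_rate: float = 3e-4
    weight_decay: float = 0.0
    decay_rate: float = 0.9
    decay_steps: int = 10_000
    pretrain_epochs: int = 2
    pretrain_batch: int = 25
    train_epochs: int = 50
    train_batch: int = 2
    augmentation_multiplier: int = 5
    augmentation_jitter_sd: float = 0.5   # raw PANSS points
    calibration: str = "platt"            # "platt" | "identity"
    seed: int = 0

    def validate(self) -> "ArchitectureConfig":
        for name in ("hidden_panss", "hidden_psp", "hidden_cgi",
                     "fusion_width", "interaction_width"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.w_mse < 0 or self.w_ce < 0:
            raise ConfigError("loss weights must be >= 0")
        return self
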