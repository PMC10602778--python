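"""Seeded synthetic cohort generator.

Emulates the statistical structure of a multicenter first-episode-psychosis
antipsychotic switching study: an enrolment of 446 with an attrition funnel
(371 phase-1 completers, 72 phase-2 completers, 66 with complete PANSS),
the published demographic margins, 48 correlated binary MINI comorbidity
items, and PANSS/PSP/CGI visit series whose endpoints are consistent with
each patient's symptomatic-remission status.

Remission is planted causally: a latent propensity

    p = sigmoid(beta0 + sum_i beta_i * x_i + gamma * s + eps)

with x_i in {-1, +1} for MINI item C_i, s the standardized baseline PANSS
total, and Gaussian noise eps, drives a Bernoulli remission outcome; symptom
trajectories are then simulated conditional on that outcome. Every stage is
reproducible from ``CohortConfig.seed`` alone.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CohortConfig, ConfigError, VISIT_WEEKS
from .mini_items import MINI_CATEGORIES, MINI_COLUMNS, N_MINI_ITEMS, mini_column
from .schema import (ANDREASEN_ITEMS, CGI_FEATURES, PANSS_ITEMS, PSP_FEATURES,
                     FeatureSchema, default_schema)

FUNNEL_FLAGS = ("completed_phase1", "continued_phase2", "completed_phase2",
                "panss_complete")
_STAGE_STATICS, _STAGE_MINI, _STAGE_OUTCOME, _STAGE_TRAJ = 1, 2, 3, 4
_STAGE_FUNNEL, _STAGE_MISSING = 5, 6


def _rng(config: CohortConfig, stage: int) -> np.random.Generator:
    # per-stage streams so funnel/missingness can be re-applied in isolation
    return np.random.default_rng([int(config.seed) % (2**31), stage])


def _draw_statics(n: int, config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    d = config.demographic_params
    occ_p = [0.25, 0.2, 0.15, 0.1, 0.3]
    deg_p = [0.1, 0.25, 0.45, 0.2]
    cols: dict[str, np.ndarray] = {}
    cols["age"] = rng.normal(d.age_mean, d.age_sd, n).clip(16, 45)
    cols["sex_male"] = (rng.random(n) < d.male_fraction).astype(int)
    cols["race"] = rng.choice(["white", "black", "asian", "other"], n,
                              p=[0.7, 0.12, 0.1, 0.08])
    cols["immigration_status"] = (rng.random(n) < 0.2).astype(int)
    cols["marital_status"] = (rng.random(n) < 0.12).astype(int)
    cols["divorce_status"] = (rng.random(n) < 0.04).astype(int)
    cols["occupation_status"] = (rng.random(n) < d.work_school_fraction).astype(int)
    occs = ["none", "manual", "clerical", "professional", "student"]
    cols["occupation_type"] = rng.choice(occs, n, p=occ_p)
    cols["previous_occupation_status"] = (rng.random(n) < 0.55).astype(int)
    cols["previous_occupation_type"] = rng.choice(occs, n, p=occ_p)
    cols["father_occupation"] = rng.choice(occs, n, p=occ_p)
    cols["mother_occupation"] = rng.choice(occs, n, p=occ_p)
    cols["years_education"] = rng.normal(12.0, 2.5, n).clip(6, 22)
    degrees = ["none", "primary", "secondary", "tertiary"]
    cols["highest_education"] = rng.choice(degrees, n, p=deg_p)
    cols["father_highest_degree"] = rng.choice(degrees, n, p=deg_p)
    cols["mother_highest_degree"] = rng.choice(degrees, n, p=deg_p)
    cols["living_status"] = (rng.random(n) < 0.6).astype(int)
    cols["dwelling"] = rng.choice(["house", "apartment", "institution", "other"],
                                  n, p=[0.45, 0.4, 0.08, 0.07])
    cols["income_source"] = rng.choice(["employment", "family", "benefits", "none"],
                                       n, p=[0.25, 0.35, 0.3, 0.1])
    cols["living_environment"] = rng.choice(["urban", "suburban", "rural"],
                                            n, p=[0.55, 0.3, 0.15])
    # diagnostic
    cols["dsm_classification"] = rng.choice(
        ["schizophrenia", "schizophreniform", "schizoaffective"], n,
        p=list(d.dsm_probs))
    shape = (d.episode_duration_mean / d.episode_duration_sd) ** 2
    scale = d.episode_duration_sd ** 2 / d.episode_duration_mean
    cols["episode_duration_months"] = rng.gamma(shape, scale, n)
    cols["current_psychiatric_treatment"] = rng.choice(
        ["none", "outpatient", "inpatient"], n, p=[0.3, 0.35, 0.35])
    cols["psychosocial_interventions"] = (rng.random(n) < 0.3).astype(int)
    cols["estimated_prognosis"] = rng.choice(["good", "fair", "poor"], n,
                                             p=[0.35, 0.45, 0.2])
    cols["admitted"] = (rng.random(n) < d.admitted_fraction).astype(int)
    # lifestyle
    cols["recreational_drugs_history"] = (rng.random(n) < 0.4).astype(int)
    cols["recreational_drugs_recent"] = (rng.random(n) < 0.2).astype(int)
    cols["caffeine_per_day"] = rng.poisson(2.0, n).astype(float)
    cols["last_caffeine"] = rng.choice(["today", "this_week", "longer"], n,
                                       p=[0.6, 0.25, 0.15])
    cols["drink_alcohol"] = (rng.random(n) < 0.5).astype(int)
    cols["alcohol_last_year"] = rng.choice(["none", "monthly", "weekly", "daily"],
                                           n, p=[0.45, 0.3, 0.2, 0.05])
    cols["smoking_status"] = (rng.random(n) < 0.55).astype(int)
    # somatic
    height = rng.normal(172.0, 10.0, n)
    weight = rng.normal(72.0, 14.0, n).clip(40, 150)
    cols["height_cm"] = height
    cols["weight_kg"] = weight
    cols["waist_cm"] = rng.normal(85.0, 12.0, n).clip(55, 140)
    cols["hip_cm"] = rng.normal(95.0, 10.0, n).clip(65, 150)
    cols["bmi"] = weight / (height / 100.0) ** 2
    cols["systolic_bp"] = rng.normal(120.0, 12.0, n)
    cols["diastolic_bp"] = rng.normal(78.0, 9.0, n)
    cols["pulse"] = rng.normal(75.0, 10.0, n)
    cols["ecg_abnormality"] = (rng.random(n) < 0.08).astype(int)
    cols["last_mealtime"] = rng.choice(["lt_2h", "2_6h", "gt_6h"], n,
                                       p=[0.4, 0.4, 0.2])
    cols["last_meal_type"] = rng.choice(["snack", "light", "full"], n,
                                        p=[0.25, 0.35, 0.4])
    cols["medication_dosage"] = rng.normal(400.0, 120.0, n).clip(50, 800)
    return pd.DataFrame(cols)


def _draw_mini(n: int, config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Hierarchical category-activation model for the 48 binary items."""
    cp = config.comorbidity_params
    items = np.zeros((n, N_MINI_ITEMS), dtype=int)
    comorbid = rng.random(n) < cp.any_rate
    cat_names = list(MINI_CATEGORIES)
    cat_active = {c: comorbid & (rng.random(n) < cp.category_rates[c])
                  for c in cat_names}
    # every comorbid patient carries >=1 active category
    none_active = comorbid.copy()
    for c in cat_names:
        none_active &= ~cat_active[c]
    cat_active[cp.forced_category] |= none_active
    for c in cat_names:
        idxs = np.array([i - 1 for i, _ in MINI_CATEGORIES[c]])
        probs = np.array([cp.item_rates.get(i + 1, 0.25) for i in idxs])
        active = cat_active[c]
        draw = rng.random((n, len(idxs))) < probs[None, :]
        draw &= active[:, None]
        # force >=1 positive item in each active category
        empty = active & ~draw.any(axis=1)
        if empty.any():
            w = probs / probs.sum()
            forced = rng.choice(len(idxs), size=int(empty.sum()), p=w)
            draw[np.flatnonzero(empty), forced] = True
        items[:, idxs] |= draw
    return pd.DataFrame(items, columns=MINI_COLUMNS)


def _draw_baseline_panss(n: int, rng: np.random.Generator) -> np.ndarray:
    """Baseline PANSS items (n x 30), acute first-episode severity."""
    z = rng.normal(0.0, 1.0, n)                       # patient severity latent
    vals = 3.8 + 0.9 * z[:, None] + rng.normal(0.0, 0.9, (n, len(PANSS_ITEMS)))
    return np.clip(np.rint(vals), 1, 7)


def remission_propensity(mini: np.ndarray, panss_total_std: np.ndarray,
                         config: CohortConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Latent P(remission) under the planted logistic model."""
    ep = config.effect_params
    x = 2.0 * mini - 1.0                              # {0,1} -> {-1,+1}
    beta = np.zeros(N_MINI_ITEMS)
    for i, b in ep.betas.items():
        beta[i - 1] = b
    eps = rng.normal(0.0, ep.noise_sd, len(x))
    logit = ep.beta0 + x @ beta + ep.gamma * panss_total_std + eps
    return expit(logit)


def simulate_trajectories(patient_row: pd.Series, config: CohortConfig,
                          seed: int) -> pd.DataFrame:
    """Visit series (one row per visit) for a single patient.

    Requires ``remission_sr`` and the baseline PANSS columns on the row;
    wraps the vectorized batch simulator.
    """
    if "remission_sr" not in patient_row:
        raise ValueError("patient must have remission_sr assigned")
    base = np.array([[patient_row[f"panss_{it}_w0"] for it in PANSS_ITEMS]])
    remit = np.array([int(patient_row["remission_sr"])])
    rng = np.random.default_rng(seed)
    panss, psp, cgi = _simulate_batch(base, remit, config, rng)
    cols: dict[str, np.ndarray] = {}
    for j, it in enumerate(PANSS_ITEMS):
        cols[f"panss_{it}"] = panss[0, :, j]
    for j, name in enumerate(PSP_FEATURES):
        cols[name] = psp[0, :, j]
    for j, name in enumerate(CGI_FEATURES):
        cols[name] = cgi[0, :, j]
    return pd.DataFrame(cols, index=pd.Index(VISIT_WEEKS, name="week"))


def _simulate_batch(baseline_panss: np.ndarray, remit: np.ndarray,
                    config: CohortConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exponential-relaxation visit series for all patients at once.

    Returns (panss, psp, cgi) of shapes (n, 6, 30), (n, 6, 5), (n, 6, 2).
    With full outcome coupling, remitters end with all severity-rule items
    <= 3 at week 8 and non-remitters violate the rule on >= 1 item.
    """
    tp = config.trajectory_params
    coupling = config.effect_params.trajectory_outcome_coupling
    n, n_items = baseline_panss.shape
    weeks = np.asarray(VISIT_WEEKS, dtype=float)
    remit_b = remit.astype(bool)
    coupled = rng.random(n) < coupling

    lo, hi = tp.nonremit_rate_range
    rates = rng.uniform(lo, hi, n)
    rlo, rhi = tp.remit_rate_range
    rates = np.where(remit_b & coupled, rng.uniform(rlo, rhi, n), rates)
    rates *= tp.decay_scale

    # PANSS endpoints: remitters relax toward mild scores, others linger
    end_remit = rng.uniform(1.0, 2.8, (n, n_items))
    end_non = baseline_panss * rng.uniform(0.75, 1.0, (n, n_items))
    good = (remit_b & coupled)[:, None]
    endpoint = np.where(good, end_remit, end_non)
    decay = np.exp(-rates[:, None, None] * weeks[None, :, None] / 8.0)
    panss = (endpoint[:, None, :]
             + (baseline_panss - endpoint)[:, None, :] * decay
             + rng.normal(0.0, tp.noise_sd, (n, len(weeks), n_items)))
    panss = np.clip(np.rint(panss), 1, 7)

    crit = np.array([PANSS_ITEMS.index(it) for it in ANDREASEN_ITEMS])
    # enforce outcome-consistent final visits for coupled patients
    force_ok = remit_b & coupled
    final = panss[:, -1, :]
    final[np.ix_(force_ok, crit)] = np.minimum(final[np.ix_(force_ok, crit)], 3)
    force_bad = ~remit_b & coupled
    if force_bad.any():
        sub = final[np.ix_(force_bad, crit)]
        ok_rows = (sub <= 3).all(axis=1)
        if ok_rows.any():
            pick = rng.integers(0, len(crit), int(ok_rows.sum()))
            rows = np.flatnonzero(force_bad)[ok_rows]
            final[rows, crit[pick]] = rng.integers(4, 6, len(rows))
    panss[:, -1, :] = final

    panss_total = panss.sum(axis=2)                        # (n, 6)
    # PSP: remitters trend upward toward better functioning
    psp_base = rng.normal(45.0, 10.0, n)
    psp_end = np.where(remit_b & coupled, rng.normal(75.0, 8.0, n),
                       rng.normal(55.0, 10.0, n))
    frac = 1.0 - np.exp(-rates[:, None] * weeks[None, :] / 8.0)
    psp_total = (psp_base[:, None] + (psp_end - psp_base)[:, None] * frac
                 + rng.normal(0.0, 2.0, (n, len(weeks)))).clip(0, 100)
    doms = (psp_total[:, :, None] / 100.0 * 6.0
            + rng.normal(0.0, 0.4, (n, len(weeks), 4))).clip(0, 6)
    psp = np.concatenate([np.rint(doms), psp_total[:, :, None]], axis=2)

    sev = (1.0 + 6.0 * (panss_total - 30.0) / 180.0
           + rng.normal(0.0, 0.3, (n, len(weeks))))
    sev = np.clip(np.rint(sev), 1, 7)
    improve_frac = (panss_total[:, :1] - panss_total) / np.maximum(
        panss_total[:, :1] - 30.0, 1.0)
    imp = np.clip(np.rint(4.0 - 3.0 * improve_frac
                          + rng.normal(0.0, 0.5, (n, len(weeks)))), 1, 7)
    cgi = np.stack([sev, imp], axis=2)
    return panss, psp, cgi


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a full cohort table (one row per patient) from the config.

    Funnel flags are initialized False; apply :func:`apply_attrition_funnel`
    to impose the study's stage counts.
    """
    config.validate()
    n = config.n_enrolled
    rng_s = _rng(config, _STAGE_STATICS)
    table = _draw_statics(n, config, rng_s)
    table.insert(0, "patient_id", [f"P{i:05d}" for i in range(1, n + 1)])
    table.insert(1, "site_id", rng_s.integers(0, config.demographic_params.n_sites, n))

    mini = _draw_mini(n, config, _rng(config, _STAGE_MINI))
    table = pd.concat([table, mini], axis=1)

    rng_o = _rng(config, _STAGE_OUTCOME)
    baseline_panss = _draw_baseline_panss(n, rng_o)
    totals = baseline_panss.sum(axis=1)
    std = (totals - totals.mean()) / max(totals.std(), 1e-12)
    p = remission_propensity(mini.to_numpy(), std, config, rng_o)
    remission = (rng_o.random(n) < p).astype(int)

    rng_t = _rng(config, _STAGE_TRAJ)
    panss, psp, cgi = _simulate_batch(baseline_panss, remission, config, rng_t)
    panss[:, 0, :] = baseline_panss                   # visit 0 is the drawn baseline
    dyn_cols: dict[str, np.ndarray] = {}
    for v, w in enumerate(VISIT_WEEKS):
        for j, it in enumerate(PANSS_ITEMS):
            dyn_cols[f"panss_{it}_w{w}"] = panss[:, v, j]
        for j, name in enumerate(PSP_FEATURES):
            dyn_cols[f"{name}_w{w}"] = psp[:, v, j]
        for j, name in enumerate(CGI_FEATURES):
            dyn_cols[f"{name}_w{w}"] = cgi[:, v, j]
    table = pd.concat([table, pd.DataFrame(dyn_cols)], axis=1)

    # CDSS/SWN gain mild dependence on mood comorbidity for realism
    mood_idx = [i - 1 for i, _ in MINI_CATEGORIES["mood"]]
    mood_any = mini.to_numpy()[:, mood_idx].any(axis=1).astype(float)
    for i in range(1, 10):
        table[f"cdss_{i}"] = rng_o.binomial(3, 0.15 + 0.25 * mood_any)
    for i in range(1, 21):
        table[f"swn_{i:02d}"] = np.clip(
            np.rint(rng_o.normal(4.2 - 0.5 * mood_any, 1.0)), 1, 6)

    for flag in FUNNEL_FLAGS:
        table[flag] = False
    table["remission_sr"] = remission
    return table


def apply_attrition_funnel(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Set funnel flags so stage counts equal ``funnel_targets`` exactly.

    Stage membership is nested (phase-2 completers are drawn from phase-2
    continuers, and so on) and seeded; visit cells beyond a patient's last
    attended visit are blanked, and phase-2 completers lacking the
    complete-PANSS flag lose one random PANSS cell.
    """
    t1, t_cont, t2, t_panss = config.funnel_targets
    n = len(cohort)
    if t1 > n:
        raise ConfigError(f"funnel target {t1} exceeds cohort size {n}")
    rng = _rng(config, _STAGE_FUNNEL)
    out = cohort.copy()
    idx = np.arange(n)
    p1 = rng.choice(idx, t1, replace=False)
    cont = rng.choice(p1, t_cont, replace=False)
    p2 = rng.choice(cont, t2, replace=False)
    pc = rng.choice(p2, t_panss, replace=False)
    for flag, members in zip(FUNNEL_FLAGS, (p1, cont, p2, pc)):
        col = np.zeros(n, dtype=bool)
        col[members] = True
        out[flag] = col

    # visit availability: phase-2 completers attend all 6 visits; phase-1
    # completers attend through week 5; early dropouts through week 2
    last_week = np.full(n, 2)
    last_week[out["completed_phase1"].to_numpy()] = 5
    last_week[out["completed_phase2"].to_numpy()] = 8
    dyn_feats = [f"panss_{it}" for it in PANSS_ITEMS] + PSP_FEATURES + CGI_FEATURES
    for w in VISIT_WEEKS:
        cols = [f"{f}_w{w}" for f in dyn_feats]
        gone = last_week < w
        if gone.any():
            out.loc[gone, cols] = np.nan
    # phase-2 completers without complete PANSS: one PANSS cell knocked out
    incomplete = np.flatnonzero(out["completed_phase2"].to_numpy()
                                & ~out["panss_complete"].to_numpy())
    for i in incomplete:
        w = VISIT_WEEKS[rng.integers(1, len(VISIT_WEEKS))]
        it = PANSS_ITEMS[rng.integers(0, len(PANSS_ITEMS))]
        out.loc[out.index[i], f"panss_{it}_w{w}"] = np.nan
    return out


def inject_missingness(cohort: pd.DataFrame, config: CohortConfig,
                       schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Independently blank static cells at each modality's configured rate.

    PANSS series of complete-PANSS patients and the outcome are never
    touched. Seeded from the config; rate 0 is the identity.
    """
    schema = schema or default_schema()
    for k, v in config.missingness_rates.items():
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"missingness rate for {k} must be in [0,1]")
    rng = _rng(config, _STAGE_MISSING)
    out = cohort.copy()
    n = len(out)
    for spec in schema.static_features:
        rate = config.missingness_rates.get(spec.modality, 0.0)
        if rate <= 0 or spec.name not in out.columns:
            continue
        mask = rng.random(n) < rate
        if mask.any():
            col = out[spec.name]
            if col.dtype.kind in "iub":
                out[spec.name] = col.astype(float)
            out.loc[mask, spec.name] = np.nan
    return out


def simulate_cohort(config: CohortConfig | None = None,
                    schema: FeatureSchema | None = None) -> pd.DataFrame:
    """Default fixture: generate, apply the attrition funnel, inject missingness."""
    config = config or CohortConfig()
    cohort = generate_cohort(config)
    cohort = apply_attrition_funnel(cohort, config)
    return inject_missingness(cohort, config, schema)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False, float_format="%.6g")


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)
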