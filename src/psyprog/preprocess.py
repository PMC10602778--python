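"""Eligibility filtering, imputation, scaling, encoding, and outcome labels.

Follows the emulated study's preprocessing rules: continuous features are
median-imputed and rescaled to [0, 1] with a robust (percentile-bounded)
min-max scaler; categorical features are mode-imputed and one-hot encoded;
binary features are mode-imputed and encoded -1/+1. Dynamic PANSS/PSP/CGI
features are scaled by their fixed instrument bounds, which keeps the
remission rule and augmentation bounds exact and leakage-free.

Symptomatic remission (SR) is the severity-only Andreasen rule: all eight
criterion items (P1, P2, P3, N1, N4, N6, G5, G9) at most 3 at the final
visit; the duration component is dropped for a 10-week horizon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import N_VISITS, VISIT_WEEKS
from .schema import (ANDREASEN_ITEMS, BINARY, CATEGORICAL, CONTINUOUS,
                     FeatureSchema, FeatureSpec, default_schema, dynamic_bounds)

logger = logging.getLogger(__name__)

FINAL_WEEK = VISIT_WEEKS[-1]


def filter_eligible(cohort: pd.DataFrame) -> pd.DataFrame:
    """Keep analysis-eligible patients: completed phase 2 with complete PANSS."""
    mask = cohort["completed_phase2"].astype(bool) & cohort["panss_complete"].astype(bool)
    return cohort.loc[mask].reset_index(drop=True)


def label_remission(panss_final_visit: pd.Series | dict) -> bool:
    """Severity-only symptomatic remission from final-visit PANSS items.

    ``panss_final_visit`` maps item short names (``p1`` .. ``g16``) to raw
    scores; remission iff every criterion item is <= 3.
    """
    vals = []
    for it in ANDREASEN_ITEMS:
        v = panss_final_visit[it]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"criterion item {it} missing; cannot label remission")
        vals.append(float(v))
    return all(v <= 3.0 for v in vals)


@dataclass
class ScalerState:
    """Fitted imputation/scaling state (training rows only)."""

    percentiles: tuple[float, float]
    medians: dict[str, float] = field(default_factory=dict)       # continuous
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    modes: dict[str, object] = field(default_factory=dict)        # cat + binary
    dyn_fill: dict[str, float] = field(default_factory=dict)      # scaled units


@dataclass
class FeatureTensorSet:
    """Model-ready encoding of a cohort table."""

    static_matrix: np.ndarray          # (N, D) floats; continuous in [0,1], binary ±1
    static_columns: list[str]
    dynamic_tensor: np.ndarray         # (N, V, F) in [0,1]
    dynamic_features: list[str]
    visit_mask: np.ndarray             # (N, V) bool
    mini_index: np.ndarray             # positions of the 48 MINI entries
    labels: np.ndarray                 # SR per patient
    labels_fr: np.ndarray
    labels_cr: np.ndarray
    patient_ids: list[str]
    site_ids: np.ndarray
    scaler_state: ScalerState

    @property
    def n_patients(self) -> int:
        return self.static_matrix.shape[0]

    def subset(self, idx) -> "FeatureTensorSet":
        idx = np.asarray(idx)
        return FeatureTensorSet(
            self.static_matrix[idx], self.static_columns,
            self.dynamic_tensor[idx], self.dynamic_features,
            self.visit_mask[idx], self.mini_index,
            self.labels[idx], self.labels_fr[idx], self.labels_cr[idx],
            [self.patient_ids[i] for i in idx], self.site_ids[idx],
            self.scaler_state)


def fit_imputer_scaler(train_table: pd.DataFrame,
                       schema: FeatureSchema | None = None,
                       percentiles: tuple[float, float] = (1.0, 99.0)) -> ScalerState:
    """Fit per-feature imputation values and robust min-max bounds.

    Continuous features get their median and the configured percentile pair
    (collapsed bounds fall back to min/max, then to a unit span); categorical
    and binary features get their mode. Raises if a feature has no observed
    training value.
    """
    if len(train_table) == 0:
        raise ValueError("training table is empty")
    schema = schema or default_schema()
    state = ScalerState(percentiles=percentiles)
    for spec in schema.static_features:
        col = train_table[spec.name]
        obs = col.dropna()
        if len(obs) == 0:
            raise ValueError(f"feature {spec.name!r} entirely missing in training data")
        if spec.value_type == CONTINUOUS:
            vals = obs.astype(float).to_numpy()
            state.medians[spec.name] = float(np.median(vals))
            lo, hi = np.percentile(vals, percentiles)
            if hi <= lo:
                lo, hi = float(vals.min()), float(vals.max())
            if hi <= lo:
                hi = lo + 1.0
            state.bounds[spec.name] = (float(lo), float(hi))
        else:
            state.modes[spec.name] = obs.mode(dropna=True).iloc[0]
    for spec in schema.dynamic_features:
        lo, hi = dynamic_bounds(spec)
        cols = [f"{spec.name}_w{w}" for w in VISIT_WEEKS]
        vals = train_table[cols].to_numpy(dtype=float)
        med = np.nanmedian(vals) if np.isfinite(vals).any() else 0.5 * (lo + hi)
        state.dyn_fill[spec.name] = float((med - lo) / (hi - lo))
    return state


def _encode_static(table: pd.DataFrame, schema: FeatureSchema,
                   state: ScalerState) -> tuple[np.ndarray, list[str], np.ndarray]:
    n = len(table)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    mini_pos: list[int] = []
    for spec in schema.static_features:
        col = table[spec.name]
        if spec.value_type == CONTINUOUS:
            vals = col.astype(float).to_numpy()
            vals = np.where(np.isnan(vals), state.medians[spec.name], vals)
            lo, hi = state.bounds[spec.name]
            blocks.append(np.clip((vals - lo) / (hi - lo), 0.0, 1.0)[:, None])
            names.append(spec.name)
        elif spec.value_type == BINARY:
            vals = col.to_numpy()
            mode = state.modes[spec.name]
            out = np.empty(n)
            for i, v in enumerate(vals):
                if pd.isna(v):
                    v = mode
                out[i] = 1.0 if float(v) > 0.5 else -1.0
            if spec.modality == "mini":
                mini_pos.append(sum(b.shape[1] for b in blocks))
            blocks.append(out[:, None])
            names.append(spec.name)
        else:
            cats = list(spec.categories)
            mode = state.modes[spec.name]
            block = np.zeros((n, len(cats)))
            unseen = 0
            for i, v in enumerate(col.to_numpy()):
                if pd.isna(v):
                    v = mode
                if v in cats:
                    block[i, cats.index(v)] = 1.0
                else:
                    unseen += 1
            if unseen:
                logger.warning("feature %s: %d unseen categories mapped to "
                               "all-zero one-hot blocks", spec.name, unseen)
            blocks.append(block)
            names.extend(f"{spec.name}={c}" for c in cats)
    return np.hstack(blocks), names, np.asarray(mini_pos)


def _encode_dynamic(table: pd.DataFrame, schema: FeatureSchema,
                    state: ScalerState) -> tuple[np.ndarray, list[str], np.ndarray]:
    n = len(table)
    feats = schema.dynamic_features
    tensor = np.full((n, N_VISITS, len(feats)), np.nan)
    for j, spec in enumerate(feats):
        lo, hi = dynamic_bounds(spec)
        for v, w in enumerate(VISIT_WEEKS):
            vals = table[f"{spec.name}_w{w}"].to_numpy(dtype=float)
            tensor[:, v, j] = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    visit_mask = np.isfinite(tensor).any(axis=2)
    # fill residual gaps: carry the previous visit forward, else the fitted fill
    for j, spec in enumerate(feats):
        fill = state.dyn_fill[spec.name]
        for v in range(N_VISITS):
            gap = visit_mask[:, v] & ~np.isfinite(tensor[:, v, j])
            if v > 0:
                prev = tensor[:, v - 1, j]
                use_prev = gap & np.isfinite(prev)
                tensor[use_prev, v, j] = prev[use_prev]
                gap &= ~use_prev
            tensor[gap, v, j] = fill
    tensor[~np.isfinite(tensor)] = 0.0                 # masked visits
    return tensor, [f.name for f in feats], visit_mask


def transform(table: pd.DataFrame, schema: FeatureSchema | None,
              state: ScalerState) -> FeatureTensorSet:
    """Encode a cohort table with a fitted state into model-ready tensors."""
    schema = schema or default_schema()
    static, names, mini_idx = _encode_static(table, schema, state)
    dyn, dyn_names, mask = _encode_dynamic(table, schema, state)
    if "remission_sr" in table.columns:
        labels = table["remission_sr"].to_numpy(dtype=int)
    else:
        crit = table[[f"panss_{it}_w{FINAL_WEEK}"
                      for it in ANDREASEN_ITEMS]].to_numpy(dtype=float)
        finite = np.isfinite(crit).all(axis=1)
        labels = np.where(finite, (crit <= 3.0).all(axis=1).astype(int), -1)
    psp_final = table[f"psp_total_w{FINAL_WEEK}"].to_numpy(dtype=float)
    cgi_final = table[f"cgi_severity_w{FINAL_WEEK}"].to_numpy(dtype=float)
    labels_fr = np.where(np.isfinite(psp_final), (psp_final >= 70).astype(int), -1)
    labels_cr = np.where(np.isfinite(cgi_final), (cgi_final <= 3).astype(int), -1)
    return FeatureTensorSet(
        static_matrix=static, static_columns=names,
        dynamic_tensor=dyn, dynamic_features=dyn_names,
        visit_mask=mask, mini_index=mini_idx,
        labels=labels, labels_fr=labels_fr, labels_cr=labels_cr,
        patient_ids=list(table["patient_id"].astype(str)),
        site_ids=table["site_id"].to_numpy(),
        scaler_state=state)


def prepare(table: pd.DataFrame, schema: FeatureSchema | None = None,
            percentiles: tuple[float, float] = (1.0, 99.0)) -> FeatureTensorSet:
    """Fit the imputer/scaler on ``table`` and transform it (single-split use)."""
    schema = schema or default_schema()
    state = fit_imputer_scaler(table, schema, percentiles)
    return transform(table, schema, state)
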