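"""Cross-validated evaluation and the with/without-comorbidity contrast.

Repeated stratified k-fold (default 20 x 10-fold) and leave-one-site-out
cross-validation with a full per-fold cycle: imputer/scaler fitted on the
training rows only, an inner calibration split, model training, and
held-out prediction. Metrics are AUC, balanced accuracy, sensitivity, and
specificity; the two model variants (with and without the 48 MINI items)
are compared per metric with a two-sided Mann-Whitney U test over paired
fold-level values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .config import ArchitectureConfig
from .model import TrainedModel, fit, predict_remission_prob
from .preprocess import FeatureTensorSet, fit_imputer_scaler, transform
from .schema import FeatureSchema, default_schema

logger = logging.getLogger(__name__)

METRICS = ("auc", "bac", "sensitivity", "specificity")


def compute_metrics(labels: np.ndarray, probabilities: np.ndarray,
                    threshold: float = 0.5) -> tuple[float, float, float, float]:
    """(AUC, BAC, sensitivity, specificity) with tied scores given 0.5 credit.

    AUC is the rank/trapezoid definition (Mann-Whitney form); with a single
    class present it is undefined and returned as NaN.
    """
    labels = np.asarray(labels).astype(int)
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    pos = labels == 1
    neg = ~pos
    if pos.any() and neg.any():
        # pairwise wins + half-credit ties, via rank arithmetic
        ranks = stats.rankdata(probabilities)
        n1, n0 = pos.sum(), neg.sum()
        auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    else:
        auc = np.nan
    pred = probabilities >= threshold
    sens = (pred & pos).sum() / pos.sum() if pos.any() else np.nan
    spec = (~pred & neg).sum() / neg.sum() if neg.any() else np.nan
    bac = np.nanmean([sens, spec])
    return float(auc), float(bac), float(sens), float(spec)


def ablate_mini(feature_set: FeatureTensorSet) -> FeatureTensorSet:
    """Drop the 48 encoded MINI columns from the static matrix."""
    if len(feature_set.mini_index) == 0:
        raise ValueError("MINI columns already ablated")
    keep = np.setdiff1d(np.arange(feature_set.static_matrix.shape[1]),
                        feature_set.mini_index)
    out = feature_set.subset(np.arange(feature_set.n_patients))
    out.static_matrix = feature_set.static_matrix[:, keep]
    out.static_columns = [feature_set.static_columns[i] for i in keep]
    out.mini_index = np.array([], dtype=int)
    return out


@dataclass
class FoldRecord:
    """One trained fold: the model, its training ids, and its test tensors."""

    model: TrainedModel
    train_ids: set
    test_set: FeatureTensorSet
    repetition: int
    fold: int
    site_held_out: int | None = None


@dataclass
class CVResult:
    metrics: pd.DataFrame                      # one row per (repetition, fold)
    folds: list[FoldRecord] = field(default_factory=list)


def _fit_fold(train_table: pd.DataFrame, test_table: pd.DataFrame,
              schema: FeatureSchema, arch: ArchitectureConfig,
              upto_visit: int, without_mini: bool,
              pretrain_bank: FeatureTensorSet | None,
              rng: np.random.Generator) -> tuple[TrainedModel, FeatureTensorSet,
                                                 np.ndarray]:
    state = fit_imputer_scaler(train_table, schema)
    train_ts = transform(train_table, schema, state)
    test_ts = transform(test_table, schema, state)
    bank = pretrain_bank
    if without_mini:
        train_ts = ablate_mini(train_ts)
        test_ts = ablate_mini(test_ts)
        bank = ablate_mini(bank) if bank is not None else None
    # inner calibration split, stratified when possible
    labels = train_ts.labels
    idx = np.arange(train_ts.n_patients)
    try:
        tr_idx, cal_idx = train_test_split(
            idx, test_size=0.2, stratify=labels,
            random_state=int(rng.integers(2**31)))
    except ValueError:
        tr_idx, cal_idx = idx, idx[:0]
    fold_arch = ArchitectureConfig(**{**arch.__dict__,
                                      "seed": int(rng.integers(2**31))})
    model = fit(train_ts.subset(tr_idx), fold_arch,
                pretrain_bank=bank,
                calibration_split=train_ts.subset(cal_idx) if len(cal_idx) else None,
                upto_visit=upto_visit)
    probs = predict_remission_prob(model, test_ts, upto_visit)
    return model, test_ts, probs


def repeated_stratified_kfold(table: pd.DataFrame, arch: ArchitectureConfig,
                              k: int = 10, repetitions: int = 20,
                              seed: int = 0, upto_visit: int = 0,
                              without_mini: bool = False,
                              schema: FeatureSchema | None = None,
                              pretrain_bank: FeatureTensorSet | None = None,
                              keep_folds: bool = True) -> CVResult:
    """Repeated stratified k-fold CV with a fresh seeded partition per repetition.

    ``table`` holds the analysis-eligible patients (one row each). Folds
    with a single outcome class in the test set record AUC as NaN with a
    warning. The returned fold records feed the explanation stage.
    """
    schema = schema or default_schema()
    if len(table) < k:
        raise ValueError(f"need at least k={k} patients, got {len(table)}")
    labels_all = table["remission_sr"].to_numpy(dtype=int)
    if len(np.unique(labels_all)) < 2:
        raise ValueError("both outcome classes must be present")
    rng = np.random.default_rng(seed)
    rows, folds = [], []
    variant = "without_mini" if without_mini else "with_mini"
    for rep in range(repetitions):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for fold_i, (tr, te) in enumerate(skf.split(table, labels_all)):
            model, test_ts, probs = _fit_fold(
                table.iloc[tr], table.iloc[te], schema, arch, upto_visit,
                without_mini, pretrain_bank, rng)
            auc, bac, sens, spec = compute_metrics(test_ts.labels, probs)
            if np.isnan(auc):
                warnings.warn(f"fold {fold_i} rep {rep}: single-class test "
                              "fold, AUC undefined", stacklevel=2)
            rows.append({"repetition": rep, "fold": fold_i, "auc": auc,
                         "bac": bac, "sensitivity": sens, "specificity": spec,
                         "n_test": len(te), "site_held_out": None,
                         "variant": variant})
            if keep_folds:
                folds.append(FoldRecord(
                    model, set(table.iloc[tr]["patient_id"].astype(str)),
                    test_ts, rep, fold_i))
    return CVResult(pd.DataFrame(rows), folds)


def leave_one_site_out(table: pd.DataFrame, arch: ArchitectureConfig,
                       seed: int = 0, upto_visit: int = 0,
                       without_mini: bool = False,
                       schema: FeatureSchema | None = None,
                       pretrain_bank: FeatureTensorSet | None = None) -> CVResult:
    """One fold per recruiting site: train on all other sites."""
    schema = schema or default_schema()
    sites = np.sort(table["site_id"].unique())
    if len(sites) < 2:
        raise ValueError("need >= 2 sites for leave-one-site-out CV")
    rng = np.random.default_rng(seed)
    rows, folds = [], []
    variant = "without_mini" if without_mini else "with_mini"
    for fold_i, site in enumerate(sites):
        te = table["site_id"] == site
        train_table, test_table = table.loc[~te], table.loc[te]
        model, test_ts, probs = _fit_fold(train_table, test_table, schema,
                                          arch, upto_visit, without_mini,
                                          pretrain_bank, rng)
        auc, bac, sens, spec = compute_metrics(test_ts.labels, probs)
        if np.isnan(auc):
            warnings.warn(f"site {site}: single-class held-out site, AUC "
                          "undefined", stacklevel=2)
        rows.append({"repetition": 0, "fold": fold_i, "auc": auc, "bac": bac,
                     "sensitivity": sens, "specificity": spec,
                     "n_test": int(te.sum()), "site_held_out": int(site),
                     "variant": variant})
        folds.append(FoldRecord(
            model, set(train_table["patient_id"].astype(str)), test_ts, 0,
            fold_i, site_held_out=int(site)))
    return CVResult(pd.DataFrame(rows), folds)


def compare_variants(metrics_with: pd.DataFrame,
                     metrics_without: pd.DataFrame) -> pd.DataFrame:
    """Per-metric Mann-Whitney U comparison over paired fold-level values.

    Requires both CV runs to share the (repetition, fold) grid; folds where
    either variant has an undefined metric are excluded pairwise (counts
    logged). Stars: * p<0.05, ** p<0.01.
    """
    a = metrics_with.set_index(["repetition", "fold"]).sort_index()
    b = metrics_without.set_index(["repetition", "fold"]).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("CV partitions differ between variants")
    rows = []
    for metric in METRICS:
        x, y = a[metric].to_numpy(), b[metric].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        dropped = int((~ok).sum())
        if dropped:
            logger.info("metric %s: %d folds excluded pairwise (undefined)",
                        metric, dropped)
        x, y = x[ok], y[ok]
        if len(x) and (np.ptp(np.concatenate([x, y])) > 0):
            _, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        else:
            p = 1.0
        stars = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
        rows.append({"metric": metric,
                     "mean_with": float(np.mean(x)) if len(x) else np.nan,
                     "sd_with": float(np.std(x, ddof=1)) if len(x) > 1 else np.nan,
                     "mean_without": float(np.mean(y)) if len(y) else np.nan,
                     "sd_without": float(np.std(y, ddof=1)) if len(y) > 1 else np.nan,
                     "p_value": float(p), "stars": stars,
                     "n_folds": len(x), "n_excluded": dropped})
    return pd.DataFrame(rows)
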