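"""Single-flip counterfactual explanation of remission predictions.

For a patient with 48 binary MINI comorbidity items, 48 counterfactual
records are generated, each flipping exactly one item; the trained
classifier predicts the remission probability for the actual record and
every counterfactual, and the per-patient feature importance map collects
the 48 signed effect sizes

    delta_i = prob(remission | C_i = yes) - prob(remission | C_i = no),

each in [-1, 1]. Flips act on the encoded -1/+1 representation (negation),
which is identical to re-encoding a yes/no flip. Maps are computed
out-of-fold: each patient is explained by the cross-validation model that
never saw them in training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mini_items import MINI_LABELS, N_MINI_ITEMS
from .model import TrainedModel, predict_remission_prob
from .preprocess import FeatureTensorSet


@dataclass
class ImportanceMap:
    patient_id: str
    effects: np.ndarray                # (48,) each in [-1, 1]
    actual_prob: float
    fold_id: int = 0
    repetition_id: int = 0

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (N_MINI_ITEMS,):
            raise ValueError(f"importance map must have {N_MINI_ITEMS} effects")


def generate_counterfactuals(record: FeatureTensorSet) -> FeatureTensorSet:
    """All 48 single-flip counterfactuals of a single encoded patient record.

    Returns a 48-row tensor set; row j differs from the input only at MINI
    item j (encoded value negated). MINI entries must be imputed (+-1).
    """
    if record.n_patients != 1:
        raise ValueError("expected a single-patient record")
    mini_idx = record.mini_index
    if len(mini_idx) != N_MINI_ITEMS:
        raise ValueError(f"record must carry {N_MINI_ITEMS} MINI entries, "
                         f"got {len(mini_idx)}")
    vals = record.static_matrix[0, mini_idx]
    if not np.all(np.isin(vals, (-1.0, 1.0))):
        raise ValueError("MINI items must be -1/+1 encoded (impute upstream)")
    out = record.subset(np.zeros(N_MINI_ITEMS, dtype=int))
    out.static_matrix = out.static_matrix.copy()
    for j, col in enumerate(mini_idx):
        out.static_matrix[j, col] = -out.static_matrix[j, col]
    return out


def effect_size(prob_yes: float, prob_no: float) -> float:
    """Signed effect prob(remission | yes) - prob(remission | no)."""
    for name, p in (("prob_yes", prob_yes), ("prob_no", prob_no)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    return float(prob_yes) - float(prob_no)


def importance_map(model: TrainedModel, record: FeatureTensorSet,
                   upto_visit: int = 0, fold_id: int = 0,
                   repetition_id: int = 0) -> ImportanceMap:
    """Per-patient importance map from 1 actual + 48 counterfactual predictions."""
    cf = generate_counterfactuals(record)
    actual = float(predict_remission_prob(model, record, upto_visit)[0])
    cf_probs = predict_remission_prob(model, cf, upto_visit)
    mini_vals = record.static_matrix[0, record.mini_index]
    effects = np.empty(N_MINI_ITEMS)
    for i in range(N_MINI_ITEMS):
        if mini_vals[i] > 0:          # actual is "yes": counterfactual is "no"
            effects[i] = effect_size(actual, cf_probs[i])
        else:
            effects[i] = effect_size(cf_probs[i], actual)
    return ImportanceMap(record.patient_ids[0], effects, actual,
                         fold_id=fold_id, repetition_id=repetition_id)


def collect_maps(fold_models: list[tuple[TrainedModel, set, FeatureTensorSet]],
                 upto_visit: int = 0,
                 repetition_id: int = 0) -> list[ImportanceMap]:
    """One map per test patient per fold, by that patient's out-of-fold model.

    ``fold_models`` holds (trained model, training patient-id set, test
    tensor set) triples; a patient appearing in both the training ids and
    the test set of the same fold trips the leakage guard.
    """
    maps: list[ImportanceMap] = []
    for fold_id, (model, train_ids, test_set) in enumerate(fold_models):
        overlap = set(test_set.patient_ids) & set(train_ids)
        if overlap:
            raise ValueError(f"leakage: patients {sorted(overlap)[:3]} in both "
                             f"train and test of fold {fold_id}")
        for i in range(test_set.n_patients):
            maps.append(importance_map(model, test_set.subset([i]), upto_visit,
                                       fold_id=fold_id,
                                       repetition_id=repetition_id))
    return maps


def maps_to_matrix(maps: list[ImportanceMap]) -> tuple[np.ndarray, list[str]]:
    """Per-patient mean importance matrix (patients x 48) across repetitions."""
    by_patient: dict[str, list[np.ndarray]] = {}
    order: list[str] = []
    for m in maps:
        if m.patient_id not in by_patient:
            by_patient[m.patient_id] = []
            order.append(m.patient_id)
        by_patient[m.patient_id].append(m.effects)
    mat = np.vstack([np.mean(by_patient[p], axis=0) for p in order])
    return mat, order


def maps_to_frame(maps: list[ImportanceMap]) -> pd.DataFrame:
    """Long-format table (patient, repetition, fold, item, label, delta)."""
    rows = []
    for m in maps:
        for i in range(N_MINI_ITEMS):
            rows.append((m.patient_id, m.repetition_id, m.fold_id, i + 1,
                         MINI_LABELS[i], m.effects[i]))
    return pd.DataFrame(rows, columns=["patient_id", "repetition", "fold",
                                       "item_id", "item_label", "delta"])
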