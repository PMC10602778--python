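"""Training procedure for the remission prognosis model.

Covers the published procedure end to end: pretraining on a synthesized
patient bank (2 epochs, batch 25), Gaussian-jitter + visit-dropout data
augmentation, training on the augmented set (50 epochs, batch 2) under the
weighted MSE + cross-entropy objective with Adam (lr 3e-4, exponential
decay 0.9 per 10,000 steps), and Platt-style probability calibration on a
held-out split. Only the SR head is calibrated and reported; FR and CR are
auxiliary multi-task heads.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .config import ArchitectureConfig
from .nn import AdamState, Batch, RemissionNetwork
from .preprocess import FeatureTensorSet

logger = logging.getLogger(__name__)

MODALITY_DIMS = {"panss": 30, "psp": 5, "cgi": 2}


class TrainingDivergedError(RuntimeError):
    """Raised when the optimization produces a non-finite loss."""


def as_batch(ts: FeatureTensorSet, idx=None) -> Batch:
    if idx is not None:
        ts = ts.subset(idx)
    return Batch(static=ts.static_matrix, dynamic=ts.dynamic_tensor,
                 mask=ts.visit_mask,
                 labels={"sr": ts.labels, "fr": ts.labels_fr, "cr": ts.labels_cr})


@dataclass
class PlattCalibration:
    """Monotone logistic map on the raw-score logit: q = sigmoid(a*l + b), a >= 0."""

    a: float = 1.0
    b: float = 0.0
    identity: bool = False

    def __call__(self, scores: np.ndarray) -> np.ndarray:
        scores = np.asarray(scores, dtype=float)
        if self.identity:
            return scores
        l = logit(np.clip(scores, 1e-7, 1 - 1e-7))
        return expit(self.a * l + self.b)


@dataclass
class TrainedModel:
    network: RemissionNetwork
    arch: ArchitectureConfig
    calibration: PlattCalibration = field(default_factory=lambda: PlattCalibration(identity=True))
    training_log: list[dict] = field(default_factory=list)


def build_model(arch: ArchitectureConfig, static_dim: int,
                modality_dims: dict[str, int] | None = None,
                zero_init: bool = False) -> TrainedModel:
    """Construct an untrained model for the given encoded static width."""
    net = RemissionNetwork(arch, static_dim, modality_dims or MODALITY_DIMS,
                           rng=np.random.default_rng(arch.seed),
                           zero_init=zero_init)
    return TrainedModel(network=net, arch=arch)


def _run_epochs(model: TrainedModel, data: FeatureTensorSet, epochs: int,
                batch_size: int, opt: AdamState, rng: np.random.Generator,
                phase: str) -> None:
    n = data.n_patients
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss, grads, parts = model.network.loss_and_grads(as_batch(data, idx))
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at {phase} epoch {epoch}, "
                    f"step {opt.step}: parts={parts}")
            opt.update(model.network.params, grads)
            epoch_loss += loss
            n_batches += 1
        model.training_log.append(
            {"phase": phase, "epoch": epoch,
             "loss": epoch_loss / max(n_batches, 1), "steps": opt.step,
             "lr": opt.learning_rate()})


def _optimizer(model: TrainedModel) -> AdamState:
    if not hasattr(model, "_opt") or model._opt is None:
        model._opt = AdamState(lr0=model.arch.learning_rate,
                               decay_rate=model.arch.decay_rate,
                               decay_steps=model.arch.decay_steps,
                               weight_decay=model.arch.weight_decay)
    return model._opt


def pretrain(model: TrainedModel, synthetic_bank: FeatureTensorSet,
             arch: ArchitectureConfig | None = None) -> TrainedModel:
    """Pretrain on a synthesized patient bank (default 2 epochs, batch 25)."""
    arch = arch or model.arch
    rng = np.random.default_rng([arch.seed, 11])
    _run_epochs(model, synthetic_bank, arch.pretrain_epochs,
                arch.pretrain_batch, _optimizer(model), rng, "pretrain")
    return model


def augment(train_set: FeatureTensorSet, arch: ArchitectureConfig,
            seed: int) -> FeatureTensorSet:
    """Expand the training set ``multiplier``-fold with jittered copies.

    Originals are kept verbatim; copies receive Gaussian jitter on the
    dynamic tensor (sd = ``augmentation_jitter_sd`` raw PANSS points,
    applied in scaled units and clipped so every value stays inside its
    instrument range) and occasional dropout of the final attended visit.
    Labels and statics are untouched.
    """
    m = int(arch.augmentation_multiplier)
    if m <= 1:
        return train_set
    rng = np.random.default_rng(seed)
    n = train_set.n_patients
    pieces = [train_set]
    sd_scaled = arch.augmentation_jitter_sd / 6.0   # PANSS span is 6 points
    for _ in range(m - 1):
        copy = train_set.subset(np.arange(n))
        jitter = rng.normal(0.0, sd_scaled, copy.dynamic_tensor.shape)
        dyn = np.clip(copy.dynamic_tensor + jitter, 0.0, 1.0)
        dyn[~copy.visit_mask] = 0.0
        mask = copy.visit_mask.copy()
        drop = rng.random(n) < 0.2
        for i in np.flatnonzero(drop):
            attended = np.flatnonzero(mask[i])
            if len(attended) > 1:
                mask[i, attended[-1]] = False
                dyn[i, attended[-1]] = 0.0
        copy.dynamic_tensor = dyn
        copy.visit_mask = mask
        pieces.append(copy)
    out = train_set.subset(np.arange(n))
    out.static_matrix = np.concatenate([p.static_matrix for p in pieces])
    out.dynamic_tensor = np.concatenate([p.dynamic_tensor for p in pieces])
    out.visit_mask = np.concatenate([p.visit_mask for p in pieces])
    out.labels = np.concatenate([p.labels for p in pieces])
    out.labels_fr = np.concatenate([p.labels_fr for p in pieces])
    out.labels_cr = np.concatenate([p.labels_cr for p in pieces])
    out.patient_ids = sum((p.patient_ids for p in pieces), [])
    out.site_ids = np.concatenate([p.site_ids for p in pieces])
    return out


def train(model: TrainedModel, augmented_set: FeatureTensorSet,
          arch: ArchitectureConfig | None = None) -> TrainedModel:
    """Main training loop (default 50 epochs at batch size 2)."""
    arch = arch or model.arch
    rng = np.random.default_rng([arch.seed, 13])
    _run_epochs(model, augmented_set, arch.train_epochs, arch.train_batch,
                _optimizer(model), rng, "train")
    return model


def calibrate(model: TrainedModel, validation_split: FeatureTensorSet,
              upto_visit: int = 0) -> TrainedModel:
    """Fit the monotone Platt map on a validation split disjoint from training.

    Single-class validation labels make the fit degenerate: the identity
    map is installed with a warning. The map is monotone by construction,
    so ranking (and AUC) is unchanged.
    """
    labels = validation_split.labels
    ok = labels >= 0
    labels = labels[ok]
    if model.arch.calibration == "identity" or len(np.unique(labels)) < 2:
        if model.arch.calibration != "identity":
            warnings.warn("single-class validation split; installing identity "
                          "calibration", stacklevel=2)
        model.calibration = PlattCalibration(identity=True)
        return model
    raw = model.network.predict_proba(as_batch(validation_split), upto_visit)[ok]
    l = logit(np.clip(raw, 1e-7, 1 - 1e-7))

    def nll(theta):
        a, b = theta
        q = expit(np.exp(a) * l + b)      # exp(a) keeps the slope positive
        q = np.clip(q, 1e-12, 1 - 1e-12)
        return -np.mean(labels * np.log(q) + (1 - labels) * np.log(1 - q))

    res = minimize(nll, x0=np.array([0.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500})
    model.calibration = PlattCalibration(a=float(np.exp(res.x[0])),
                                         b=float(res.x[1]))
    return model


def predict_remission_prob(model: TrainedModel, tensors: FeatureTensorSet,
                           upto_visit: int = 0) -> np.ndarray:
    """Calibrated SR probability per patient using visits 0..``upto_visit``."""
    raw = model.network.predict_proba(as_batch(tensors), upto_visit)
    return model.calibration(raw)


def fit(train_set: FeatureTensorSet, arch: ArchitectureConfig,
        pretrain_bank: FeatureTensorSet | None = None,
        calibration_split: FeatureTensorSet | None = None,
        upto_visit: int = 0, augment_seed: int | None = None) -> TrainedModel:
    """Convenience wrapper chaining build -> pretrain -> augment -> train -> calibrate."""
    model = build_model(arch, train_set.static_matrix.shape[1])
    if pretrain_bank is not None:
        pretrain(model, pretrain_bank, arch)
    aug = augment(train_set, arch,
                  augment_seed if augment_seed is not None else arch.seed + 29)
    train(model, aug, arch)
    if calibration_split is not None:
        calibrate(model, calibration_split, upto_visit)
    return model
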