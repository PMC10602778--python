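"""Network mechanics and the training procedure."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from psyprog.config import ArchitectureConfig
from psyprog.model import (as_batch, augment, build_model, calibrate, fit,
                           predict_remission_prob, pretrain, train)
from psyprog.nn import AdamState, Batch, RemissionNetwork
from psyprog.evaluation import compute_metrics
from psyprog.preprocess import prepare

from conftest import planted_cohort

TOY_ARCH = ArchitectureConfig(hidden_panss=3, hidden_psp=2, hidden_cgi=2,
                              fusion_width=4, interaction_width=3, seed=1)
TOY_DIMS = {"panss": 4, "psp": 2, "cgi": 1}


def toy_batch(seed=0, B=3, T=4):
    rng = np.random.default_rng(seed)
    return Batch(static=rng.normal(size=(B, 5)),
                 dynamic=rng.random((B, T, 7)),
                 mask=np.array([[1, 1, 1, 0], [1, 1, 1, 1], [1, 0, 0, 0]],
                               dtype=bool),
                 labels={"sr": np.array([1, 0, 1]),
                         "fr": np.array([0, 1, -1]),
                         "cr": np.array([1, 1, 0])})


class TestNetworkMechanics:
    def test_parameter_count_matches_closed_form(self):
        # hand count for a 2-unit toy: per LSTM d*4h + h*4h + 4h; fusion
        # (sum_h + Ds)*F + F; per head F*I + I + I*2 + 2; regression F*Dd + Dd
        arch = ArchitectureConfig(hidden_panss=2, hidden_psp=2, hidden_cgi=2,
                                  fusion_width=3, interaction_width=2, seed=0)
        dims = {"panss": 3, "psp": 2, "cgi": 1}
        net = RemissionNetwork(arch, static_dim=4, modality_dims=dims)
        lstm = sum(d * 8 + 2 * 8 + 8 for d in dims.values())
        fusion = (6 + 4) * 3 + 3
        heads = 3 * (3 * 2 + 2 + 2 * 2 + 2)
        reg = 3 * 6 + 6
        assert net.n_parameters() == lstm + fusion + heads + reg

    def test_class_probabilities_normalized_each_timestep(self):
        net = RemissionNetwork(TOY_ARCH, 5, TOY_DIMS)
        fwd = net.forward(toy_batch())
        for head in ("sr", "fr", "cr"):
            sums = fwd[f"probs_{head}"].sum(axis=2)
            assert np.allclose(sums, 1.0, atol=1e-6)

    def test_zero_init_network_is_constant(self):
        net = RemissionNetwork(TOY_ARCH, 5, TOY_DIMS, zero_init=True)
        p1 = net.predict_proba(toy_batch(seed=1), upto_visit=1)
        p2 = net.predict_proba(toy_batch(seed=2), upto_visit=1)
        assert np.allclose(p1, 0.5) and np.allclose(p2, 0.5)

    def test_gradients_match_numerical_differentiation(self):
        net = RemissionNetwork(TOY_ARCH, 5, TOY_DIMS)
        batch = toy_batch()
        loss, grads, _ = net.loss_and_grads(batch)
        rng = np.random.default_rng(2)
        eps = 1e-6
        for key, val in net.params.items():
            for flat in rng.choice(val.size, size=min(3, val.size),
                                   replace=False):
                ix = np.unravel_index(flat, val.shape)
                orig = val[ix]
                val[ix] = orig + eps
                lp, _, _ = net.loss_and_grads(batch)
                val[ix] = orig - eps
                lm, _, _ = net.loss_and_grads(batch)
                val[ix] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][ix] == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_zero_mse_weight_excludes_regression_gradient(self):
        arch = dataclasses.replace(TOY_ARCH, w_mse=0.0)
        net = RemissionNetwork(arch, 5, TOY_DIMS)
        _, grads, _ = net.loss_and_grads(toy_batch())
        assert np.all(grads["W_reg"] == 0.0)
        assert np.any(grads["W_fuse"] != 0.0)

    def test_missing_modality_rejected(self):
        with pytest.raises(ValueError, match="cgi"):
            RemissionNetwork(TOY_ARCH, 5, {"panss": 4, "psp": 2})


class TestOptimizerSchedule:
    def test_exponential_decay_value_at_decay_steps(self):
        opt = AdamState(lr0=3e-4, decay_rate=0.9, decay_steps=10_000)
        assert opt.learning_rate(step=10_000) == pytest.approx(2.7e-4)
        assert opt.learning_rate(step=0) == pytest.approx(3e-4)


class TestTrainingProcedure:
    def test_pretrain_step_count(self, schema, smoke_arch):
        bank = prepare(planted_cohort(20, n=100), schema)
        arch = dataclasses.replace(smoke_arch, pretrain_epochs=2,
                                   pretrain_batch=25)
        model = build_model(arch, bank.static_matrix.shape[1])
        pretrain(model, bank, arch)
        assert model._opt.step == 8          # 2 epochs x ceil(100/25)

    def test_zero_epochs_leaves_parameters_unchanged(self, schema, smoke_arch):
        bank = prepare(planted_cohort(21, n=30), schema)
        arch = dataclasses.replace(smoke_arch, pretrain_epochs=0)
        model = build_model(arch, bank.static_matrix.shape[1])
        before = {k: v.copy() for k, v in model.network.params.items()}
        pretrain(model, bank, arch)
        for k, v in model.network.params.items():
            assert np.array_equal(before[k], v)

    def test_pretraining_descends_training_loss(self, schema, smoke_arch):
        wins = 0
        for seed in range(10):
            bank = prepare(planted_cohort(30 + seed, n=60, coupling=1.0), schema)
            arch = dataclasses.replace(smoke_arch, seed=seed,
                                       pretrain_epochs=4, pretrain_batch=10)
            model = build_model(arch, bank.static_matrix.shape[1])
            from psyprog.model import as_batch
            loss_before, _, _ = model.network.loss_and_grads(as_batch(bank))
            pretrain(model, bank, arch)
            loss_after, _, _ = model.network.loss_and_grads(as_batch(bank))
            wins += loss_after <= loss_before
        assert wins >= 9

    def test_training_determinism(self, schema, smoke_arch):
        data = prepare(planted_cohort(22, n=40, coupling=1.0), schema)
        probs = []
        for _ in range(2):
            model = build_model(smoke_arch, data.static_matrix.shape[1])
            train(model, data, dataclasses.replace(smoke_arch, train_epochs=2))
            probs.append(predict_remission_prob(model, data, upto_visit=0))
        assert np.array_equal(probs[0], probs[1])


class TestAugmentation:
    def test_multiplier_one_is_identity(self, tiny_tensorset, smoke_arch):
        arch = dataclasses.replace(smoke_arch, augmentation_multiplier=1)
        assert augment(tiny_tensorset, arch, seed=0) is tiny_tensorset

    def test_multiplier_counts_and_originals_preserved(self, tiny_tensorset,
                                                       smoke_arch):
        arch = dataclasses.replace(smoke_arch, augmentation_multiplier=5)
        out = augment(tiny_tensorset, arch, seed=0)
        n = tiny_tensorset.n_patients
        assert out.n_patients == 5 * n
        assert np.array_equal(out.dynamic_tensor[:n],
                              tiny_tensorset.dynamic_tensor)
        assert np.array_equal(out.labels, np.tile(tiny_tensorset.labels, 5))

    def test_jittered_values_stay_in_instrument_bounds(self, tiny_tensorset,
                                                       smoke_arch):
        arch = dataclasses.replace(smoke_arch, augmentation_multiplier=10)
        out = augment(tiny_tensorset, arch, seed=1)
        assert out.dynamic_tensor.min() >= 0.0
        assert out.dynamic_tensor.max() <= 1.0


class TestCalibration:
    def _trained(self, schema, smoke_arch, seed=0):
        data = prepare(planted_cohort(40 + seed, n=80, betas={1: -2.0},
                                      coupling=1.0), schema)
        model = build_model(dataclasses.replace(smoke_arch, seed=seed),
                            data.static_matrix.shape[1])
        train(model, data, dataclasses.replace(smoke_arch, train_epochs=3))
        return model, data

    def test_calibration_preserves_auc(self, schema, smoke_arch):
        model, data = self._trained(schema, smoke_arch)
        raw = model.network.predict_proba(as_batch(data), 0)
        calibrate(model, data, upto_visit=0)
        cal = predict_remission_prob(model, data, upto_visit=0)
        auc_raw, *_ = compute_metrics(data.labels, raw)
        auc_cal, *_ = compute_metrics(data.labels, cal)
        assert auc_cal == pytest.approx(auc_raw, abs=1e-12)

    def test_single_class_split_installs_identity_with_warning(self, schema,
                                                               smoke_arch):
        model, data = self._trained(schema, smoke_arch, seed=1)
        degenerate = data.subset(np.flatnonzero(data.labels == 1))
        with pytest.warns(UserWarning, match="single-class"):
            calibrate(model, degenerate, upto_visit=0)
        assert model.calibration.identity

    def test_identity_on_well_calibrated_scores(self):
        # known-calibration simulation: labels ~ Bernoulli(score)
        from psyprog.model import TrainedModel
        rng = np.random.default_rng(3)
        n = 2000
        scores = rng.uniform(0.05, 0.95, n)
        labels = (rng.random(n) < scores).astype(int)

        class _Stub:
            def predict_proba(self, batch, upto_visit, head="sr"):
                return scores

        class _Split:
            static_matrix = np.zeros((n, 1))
            dynamic_tensor = np.zeros((n, 1, 1))
            visit_mask = np.ones((n, 1), dtype=bool)
            labels_fr = labels
            labels_cr = labels

        split = _Split()
        split.labels = labels
        model = TrainedModel(network=_Stub(), arch=ArchitectureConfig())
        calibrate(model, split, upto_visit=0)
        out = model.calibration(scores)
        assert np.max(np.abs(out - scores)) < 0.05


class TestPrediction:
    def test_probability_range_and_determinism(self, schema, smoke_arch):
        data = prepare(planted_cohort(50, n=60, coupling=1.0), schema)
        model = fit(data, dataclasses.replace(smoke_arch, train_epochs=2))
        p1 = predict_remission_prob(model, data, upto_visit=0)
        p2 = predict_remission_prob(model, data, upto_visit=0)
        assert np.array_equal(p1, p2)
        assert p1.min() >= 0.0 and p1.max() <= 1.0

    def test_out_of_schedule_visit_rejected(self, schema, smoke_arch):
        data = prepare(planted_cohort(51, n=20), schema)
        model = build_model(smoke_arch, data.static_matrix.shape[1])
        with pytest.raises(ValueError, match="upto_visit"):
            predict_remission_prob(model, data, upto_visit=7)

    def test_planted_effect_direction_in_predictions(self, schema, smoke_arch):
        cohort = planted_cohort(52, n=600, betas={1: -2.0}, noise_sd=0.5)
        data = prepare(cohort, schema)
        model = fit(data, dataclasses.replace(smoke_arch, seed=3))
        probs = predict_remission_prob(model, data, upto_visit=0)
        yes = probs[cohort["mini_01"].to_numpy() == 1].mean()
        no = probs[cohort["mini_01"].to_numpy() == 0].mean()
        assert yes < no

    def test_learnability_strong_signal_vs_pure_null(self, schema, smoke_arch):
        from psyprog.config import (CohortConfig, ComorbidityParams,
                                    EffectParams, _default_category_rates,
                                    _default_item_rates)
        from psyprog.cohort import generate_cohort
        from psyprog.evaluation import repeated_stratified_kfold
        # strong planted effect at ~50% prevalence
        cr = _default_category_rates(); cr["mood"] = 1.0
        ir = _default_item_rates(); ir[1] = 0.5
        eff = EffectParams(beta0=0.0, betas={1: -3.0}, gamma=0.0,
                           noise_sd=0.25, trajectory_outcome_coupling=0.0)
        cfg = CohortConfig(n_enrolled=600, funnel_targets=(600,) * 4,
                           comorbidity_params=ComorbidityParams(
                               any_rate=1.0, category_rates=cr, item_rates=ir),
                           effect_params=eff, seed=11)
        cohort = generate_cohort(cfg)
        for f in ("completed_phase1", "continued_phase2", "completed_phase2",
                  "panss_complete"):
            cohort[f] = True
        strong = repeated_stratified_kfold(cohort, smoke_arch, k=3,
                                           repetitions=1, seed=11,
                                           keep_folds=False)
        assert strong.metrics["auc"].mean() > 0.75
        null_cohort = planted_cohort(11, n=600, betas={}, noise_sd=1.0)
        null = repeated_stratified_kfold(null_cohort, smoke_arch, k=3,
                                         repetitions=1, seed=11,
                                         keep_folds=False)
        assert abs(null.metrics["auc"].mean() - 0.5) < 0.07
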