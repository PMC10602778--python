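"""Single-flip counterfactual explanation for one patient.

Trains the prognosis model on a cohort with a strong planted depression
effect, then builds the importance map of a held-out patient: 48
counterfactual records (one comorbidity item flipped each), 49 model
evaluations, and the signed effect sizes

    delta_i = P(remission | C_i = yes) - P(remission | C_i = no).

The planted item ("major depressive episode: current") should carry the
most negative delta.
"""

import numpy as np

from psyprog import (ArchitectureConfig, CohortConfig, EffectParams,
                     generate_cohort, fit, importance_map, prepare)
from psyprog.mini_items import MINI_LABELS

n = 400
cfg = CohortConfig(n_enrolled=n, funnel_targets=(n, n, n, n), seed=2,
                   effect_params=EffectParams(betas={1: -2.0}, gamma=-0.5,
                                              noise_sd=0.8))
cohort = generate_cohort(cfg)
for flag in ("completed_phase1", "continued_phase2", "completed_phase2",
             "panss_complete"):
    cohort[flag] = True

train, test = cohort.iloc[:360], cohort.iloc[360:]
encoded_train = prepare(train)
encoded_test = prepare(test)     # illustration only; CV handles this properly

arch = ArchitectureConfig(hidden_panss=8, hidden_psp=4, hidden_cgi=4,
                          fusion_width=24, interaction_width=12,
                          train_epochs=8, train_batch=8,
                          augmentation_multiplier=1, learning_rate=3e-3,
                          seed=2)
model = fit(encoded_train, arch)

patient = encoded_test.subset([0])
m = importance_map(model, patient, upto_visit=0)
print(f"patient {m.patient_id}: predicted P(remission) = {m.actual_prob:.3f}")
print()
order = np.argsort(m.effects)
print("strongest negative comorbidity effects on this prediction:")
for j in order[:3]:
    print(f"  {MINI_LABELS[j]:<55s} delta = {m.effects[j]:+.3f}")
print("strongest positive:")
for j in order[-2:]:
    print(f"  {MINI_LABELS[j]:<55s} delta = {m.effects[j]:+.3f}")
print()
print("each delta is the change in predicted remission probability when")
print("only that one yes/no interview item is flipped.")
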