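# psyprog

Counterfactual explanation of psychiatric-comorbidity effects in remission
prediction for first-episode psychosis — built as a reusable, fully tested
pipeline over a calibrated synthetic cohort simulator.

## The problem

Patients with first-episode psychosis frequently carry additional
psychiatric diagnoses (depression, anxiety, substance use, suicidality),
and clinicians would like to know how each of those comorbidities shifts a
patient's chance of *symptomatic remission* under antipsychotic treatment.
A multi-modal recurrent classifier can predict remission from baseline
characteristics and repeated symptom measurements, but a prediction alone
does not say *which* comorbidity is doing the work. The counterfactual
approach answers that directly: flip one yes/no interview item at a time,
re-run the classifier, and read off the change in predicted probability.

For patient *p* and MINI comorbidity item *Cᵢ* (48 binary items), the
per-patient effect size is

    Δᵢ(p) = P(remission | Cᵢ = yes) − P(remission | Cᵢ = no),  Δᵢ ∈ [−1, 1],

computed out-of-fold with one actual and 48 single-flip counterfactual
model evaluations. The pipeline then:

1. **trains** the classifier (per-modality LSTMs over PANSS/PSP/CGI visit
   series fused with static features; multi-task SR/FR/CR heads; Adam,
   augmentation, Platt calibration) under repeated stratified k-fold or
   leave-one-site-out cross-validation, with and without the MINI items;
2. **explains** every patient with a 48-entry importance map;
3. **tests** each item's group-level effect against a bootstrapped null
   with Bonferroni-corrected Wilcoxon rank-sum machinery and rank-sum
   effect sizes r = |Z|/√(2N);
4. **clusters** the per-patient maps (Ward linkage, k = 2) to expose
   subgroups whose predictions react differently to comorbidity flips.

Because the original multicenter cohort is not publicly available, the
package ships a seeded simulator calibrated to the published sample
structure (446 enrolled → 371 → 72 → 66 analysis patients; 79% male, mean
age 25.3, 55% admitted, 30% any comorbidity, 20% current suicidality, …)
with comorbidity effects *planted* through a logistic propensity model —
so every claim in the test suite is a parameter-recovery result. See
`docs/methods.md` for the model, assumptions, and design choices.

## Worked example

`examples/04_full_pipeline.py` runs the whole pipeline on a 450-patient
synthetic cohort with a planted negative effect on "major depressive
episode: current" (β = −2.0) and a planted positive effect on
"suicidality: current" (β = +1.5):

```
$ python examples/04_full_pipeline.py
group effects, sorted most negative first (top and bottom 3):
                       item_label  median  p_value  r_value  significant
major depressive episode: current  -0.071    0.001    0.710         True
   major depressive episode: past  -0.026    0.118    0.627        False
                  dysthymia: past  -0.023    0.159    0.585        False
...
                         item_label  median  p_value  r_value  significant
            panic disorder: current   0.018    0.215    0.446        False
posttraumatic stress disorder: past   0.020    0.190    0.549        False
               suicidality: current   0.042    0.013    0.660        False

two-cluster solution: sizes [292, 108], limited-effect cluster = 0 (73% of patients)
```

Reading this: flipping the current-depression item to "yes" lowers the
predicted remission probability by 0.071 for the median patient — the item
is recovered as the most negative group effect and is the only one to
survive Bonferroni correction, while the planted positive item lands at
the opposite extreme. Correlated mood items inherit mild negative medians
through their co-occurrence with the planted item. The two-cluster cut
separates a majority whose predictions barely react to any flip from a
minority with strong comorbidity effects. Other examples cover the
simulator, the model-variant comparison, and a single-patient explanation.

There is also a thin CLI:

```sh
psyprog simulate --seed 0 --out cohort.csv
psyprog preprocess --cohort cohort.csv --out eligible.csv
psyprog run-all --config run.yaml --out results/
```

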