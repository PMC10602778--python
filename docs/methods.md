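# Methods

`psyprog` re-implements, as a tested pipeline over synthetic data, an
analysis workflow for first-episode psychosis cohorts: a recurrent
multi-modal classifier predicts symptomatic remission, a single-flip
counterfactual engine turns the classifier into per-patient comorbidity
importance maps, group-level statistics summarize those maps across
patients, and Ward clustering looks for patient subtypes in them. The
original cohort data are not publicly available, so the package ships a
calibrated simulator and every result in the test suite is a
parameter-recovery statement about synthetic data, not a reproduction of
clinical findings.

## The synthetic cohort

One simulated patient carries seven static modalities (demographic,
diagnostic, lifestyle, somatic, treatment, CDSS, SWN), 48 binary MINI
comorbidity items, and three dynamic modalities — PANSS (30 items, each
1–7), PSP (5 features) and CGI (2 features) — at six visits (baseline and
weeks 2, 3, 5, 6, 8).

**Margins.** The generator is calibrated to the study sample it emulates:
446 enrolled with an attrition funnel of 371 phase-1 completers, 72
phase-2 completers and 66 patients with complete PANSS; 79% male, mean age
25.3 y (SD 5 y — the printed 0.8 is only plausible as a standard error),
55% admitted, DSM split 67/31.5/1.5, mean episode duration 2.5 months
(Gamma, SD 1.5), 32% in work or school. Funnel stage counts are met
*exactly* by seeded assignment; marginal rates are Bernoulli draws and
match within binomial error.

**Comorbidity co-occurrence.** The 48 items follow a hierarchical
category-activation model: a Bernoulli(0.30) gate selects comorbid
patients; for them, diagnostic categories (mood, suicidality, anxiety,
eating, somatoform, alcohol, substance, other) activate independently at
conditional rates chosen so the marginals are 21% mood, 18% anxiety, 5%
substance use and 20% current suicidality; items within an active category
then switch on at configurable conditional rates, with at least one item
forced per active category and at least one category per comorbid patient.
This construction is exactly calibratable to every target rate, produces
block-structured co-occurrence, and makes "any positive item" equal the
30% gate. Current suicidality is nested inside the comorbid subgroup,
which reconciles the 20% marginal with the 30% any-comorbidity figure.
The item catalogue itself is a synthetic stand-in for the (non-public)
MINI-PLUS list, with the five items that have published indices pinned to
their positions.

**Planted outcome model.** Remission is drawn from
`p = sigmoid(β₀ + Σᵢ βᵢ xᵢ + γ·s + ε)` with `xᵢ ∈ {−1,+1}` the encoded
items, `s` the standardized baseline PANSS total, and `ε ~ N(0, σ)`.
Defaults plant the qualitative structure reported for the real cohort:
negative coefficients on the depressive-episode items (−0.8, −0.6, −0.5),
positive on current suicidality and recent substance abuse (+0.7 each),
γ = −0.5, σ = 1. Under this model the single-flip effect size has a
closed-form counterpart, which the oracle tests exploit.

**Trajectories.** Each dynamic feature relaxes exponentially from its
baseline toward an endpoint, `v(w) = e + (b − e)·exp(−r·w/8)`, with faster
rates and milder endpoints for remitters, plus bounded observation noise.
With full outcome coupling (the default), remitters end with all eight
severity-rule items ≤ 3 at week 8 and non-remitters violate the rule on at
least one item, so the severity-only remission label derived from PANSS
coincides with the planted outcome. Setting the coupling to 0 makes
trajectories outcome-blind — the configuration used when an experiment
needs the outcome signal confined to the MINI items.

**What the simulator does not emulate:** site effects on features (sites
are assigned but exchangeable), informative dropout (funnel membership is
random), item-level measurement error in the interview, pharmacological
differences between treatment arms, and somatic comorbidity. Passing
tests therefore demonstrate that the pipeline recovers planted structure
under a faithful data layout — not that the clinical findings replicate.

## Preprocessing

Continuous statics: median imputation, then percentile-bounded min–max
scaling (1st/99th by default) with clipping into [0,1], fitted on training
rows only. Categorical statics: mode imputation, one-hot encoding;
categories unseen at transform time map to an all-zero block (logged)
rather than erroring, so rare categories cannot crash a CV fold. Binary
statics (including the MINI items): mode imputation, −1/+1 encoding.
Dynamic features are scaled by fixed instrument bounds (PANSS 1–7, CGI
1–7, PSP domains 0–6, PSP total 0–100), which keeps the remission rule and
the augmentation-jitter bounds exact and removes any leakage pathway
through the dynamic scaler. Remission (SR) is the severity-only rule —
P1, P2, P3, N1, N4, N6, G5, G9 all ≤ 3 at the final visit — because a
10-week trial cannot support a 6-month duration component. Auxiliary
labels for the FR/CR heads derive from final-visit PSP total ≥ 70 and CGI
severity ≤ 3.

## The prognosis model

One LSTM branch per dynamic modality; at each timestep the branch hidden
states are concatenated with the static vector into a tanh fusion layer,
followed by per-outcome time-distributed interaction layers, softmax class
heads for SR/FR/CR at the next visit, and a linear regression of the next
visit's dynamic vector. The loss is `w_mse·MSE + w_ce·CE` (both weights
default 1), evaluated only at attended visits. Training follows the
published procedure: optional pretraining on a separately-seeded synthetic
bank (2 epochs, batch 25), augmentation (Gaussian jitter of sd 0.5 PANSS
points on dynamics plus occasional final-visit dropout, ×5 by default),
main training (50 epochs, batch 2 by default) with Adam at 3·10⁻⁴ and
exponential decay (×0.9 per 10,000 steps), then Platt-style monotone
calibration of the SR probability on an inner validation fold (monotone by
construction, so discrimination is untouched; a single-class fold installs
the identity map with a warning). The network and backpropagation are
implemented directly in NumPy; gradients are checked against numerical
differentiation in the test suite, and training is bit-reproducible given
the seed. Hidden sizes (16/16/16, fusion 64, interaction 32) are defaults
for a ~66-patient sample; the smoke experiments in the tests use smaller
widths, fewer epochs and a larger learning rate (3·10⁻³) purely to keep
many seeded replicates cheap.

Predictions default to `upto_visit = 0` (baseline only): with later visits
included, the PANSS course itself nearly determines the label and the
static comorbidity items would be explained out of the model.

## Counterfactual importance maps

For each patient, each of the 48 items is flipped once on the encoded
−1/+1 representation (negation ≡ re-encoding the flipped interview
answer), giving 49 model evaluations per map. The effect size is
`Δᵢ = P(remission | Cᵢ = yes) − P(remission | Cᵢ = no)`, signed by that
convention regardless of the patient's actual answer, so `Δᵢ ∈ [−1, 1]`.
Maps are computed strictly out-of-fold (a leakage guard refuses a patient
explained by a model that saw them), and a patient's per-repetition maps
are averaged into one map per patient for group statistics and clustering.

## Group-level inference

Per item: median and quartiles of Δ across patients, a bootstrapped null
bank, Wilcoxon rank-sum tests against the bank, and the effect size
`r = |Z|/√(2N)` averaged over bootstrap replicates (and CV repetitions
when available). The bank resamples patient-sized vectors from the pooled
48×N effects after grand-median centering, so it preserves both the
within-item spread and the across-item spread of typical (mostly null)
item effects.

The *flagging* p-value needs one extra step. A trained classifier always
carries small systematic weights on noise items — finite-sample
feature–outcome correlations of order 1/√n — so every item's Δ
distribution is slightly location-shifted, and a rank-sum test at N in the
hundreds will flag dozens of such items however the bank is built; no
training-intensity, regularization or centering choice removes this (we
verified empirically across learning rates, epochs, weight decay and both
centering recipes). Those noise shifts do, however, share one
distribution across the 48 items. The default test therefore standardizes
each item's median effect by the across-item mean and SD and reads the
two-sided tail of a t(12) reference; the small df reflects that the items
form roughly 8–12 correlated diagnostic blocks, so far fewer than 48
effectively independent medians enter the scale estimate, and the heavier
tail absorbs the block-induced excess kurtosis. At smoke scale this
leaves zero Bonferroni flags in 12/12 fully-null pipeline runs while a
planted β = −2 item is recovered in 8/8 runs at p ≈ 4·10⁻⁵. The literal
median-over-replicates rank-sum p remains available
(`p_mode="replicate_median"`) and is always reported alongside, as is an
item-centered bank (`recipe="item_centered"`). Bonferroni flags are
computed at α = 0.05 and α = 0.001; rows are sorted by median with ties
broken by item index.

## Clustering

Ward linkage on Euclidean distances between the raw (unstandardized)
per-patient maps — all 48 coordinates already share the probability scale
— cut at k = 2 for the headline solution (k is configurable). Labels are
relabeled by order of first appearance, so the output is deterministic up
to input order, and shuffling patients changes labels only by renaming.
The cluster whose mean map has the smaller L1 norm is reported as the
"limited-effect" subgroup, with sizes, both norms and the subgroup
fraction; exact ties break toward the lower id and are flagged.

## Evaluation protocol

Repeated stratified k-fold (defaults 20 × 10) and leave-one-site-out CV,
with the imputer/scaler, augmentation and calibration all fitted inside
each training fold. Stratification keeps both outcome classes in the
small folds a 66-patient sample produces. Metrics: AUC (rank form, ties
at half credit; undefined on single-class folds and recorded as missing
with a warning), sensitivity and specificity at threshold 0.5 on the
calibrated probability, and balanced accuracy. The with/without-MINI
contrast is a two-sided Mann–Whitney U per metric over paired fold-level
values (the finest grain available), excluding pairwise any fold where
either variant's metric is undefined.

## Problem sizes in the test suite

The seeded full-pipeline batteries run at smoke scale, chosen once as the
smallest conditions at which the planted effects are comfortably inside
the detection region: recovery, 8 seeds × 600 patients (β_depression =
−2), 3-fold CV × 2 repetitions, B = 200, requiring ≥ 7/8 recoveries;
type-I, 10 seeds × 300 patients with all β = 0, requiring zero flags in
≥ 9/10; ablation, 10 seeds × 600 patients with signal only in the MINI
items, requiring the with-comorbidity AUC to win in ≥ 9/10. These mirror
the full-scale ≥ 90/100 and ≥ 95/100 batteries at the same proportions.

## Known limitations

The across-item standardization assumes most items are null (it is a
median-of-noise reference); with many strong simultaneous effects its
scale inflates and weaker true effects lose flags — conservative, not
anticonservative. The r-values reported for strongly separated items
saturate near the rank-sum ceiling and should be read as "large", not as
point estimates. The simulator's trajectory model is a two-parameter
relaxation, adequate for testing the pipeline's use of visit series but
not a pharmacodynamic model. Leave-one-site-out results on synthetic data
are exchangeable across sites by construction and say nothing about real
cross-site transport.
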