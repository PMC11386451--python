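# Methods

## Model and rationale

The package studies one training intervention for patch-level MSI/MSS
histology classifiers: replacing the binary target with a three-way
target in which the MSI class is split into two genomically-defined
sub-classes. Labels are assigned per patient and propagated to all of
the patient's patches (no within-patient genomic heterogeneity is
modelled). Three schemes are provided:

- **SNP threshold** — MSI patients with SNP count strictly greater than
  a threshold become `MSI2`, the rest `MSI1`; equality goes to `MSI1`.
  The default threshold is 1200, the optimum of a sweep over 800–1500
  (step 100, configurable) selected by patient-level validation AUROC
  with ties broken toward the smaller threshold.
- **CIMP category** — MSI splits into `MSI-CIMP-H` vs `MSI-NON-CIMP-H`.
  Because CIMP-H is rare among MSS patients, CIMP-H MSS patients are
  excluded from *training* data (never from test data) to sharpen the
  MSS phenotype.
- **CNV threshold** — same rule as SNP with default threshold 0.005.
  CNV is deliberately uncoupled from morphology in the default
  simulator, making this scheme a randomization control.

At inference only images are used. A patch's MSI probability is the
maximum of its two MSI sub-class softmax outputs (taken per patch), and
a patient's MSI score is the arithmetic mean of their patches' MSI
probabilities. The order — max, then mean — is fixed; the collapsed
pipeline is tested for exact equivalence with the documented
formulation.

Two decomposed models can be fused: per patch, the two 3-class
probability rows are concatenated into a 6-vector and fed to a small
MLP (one hidden layer of 16 units) that emits binary MSS/MSI
probabilities. The constituents are frozen; the fusion is a pure
function of their probabilities. Fusion training follows a
cross-validated stacking protocol: each constituent is trained once per
fold, the MLP is fitted to the pooled *out-of-fold* predictions (every
training patch scored by the one model that did not see it), and at
test time it is applied to the fold-averaged constituent predictions.
A single-fold variant was measurably worse: when the two sub-labellings
track the same latent structure the constituents are redundant, fusion
can at best match the better one, and a fusion trained on ~300 patches
from ~50 patients interpolates below it.

## Training stack

There is no deep-learning framework in the dependency set, and none is
needed at this problem scale. The classifier is a fixed convolutional
featurizer with a trainable linear softmax head:

- **Featurizer** — 32 random 5×5×3 filters (zero-mean, unit-norm, drawn
  once from a dedicated `backbone_seed`), applied with stride 2, ReLU,
  then a 3×3 spatial average-pooling grid, concatenated with per-channel
  colour means and standard deviations (294 features for 64 px patches).
  Fixing the filters makes the baseline-vs-decomposed comparison
  airtight: the two models share every feature and differ only in head
  width (2 vs 3), so any performance gap is attributable to the label
  decomposition.
- **Head** — multinomial logistic regression trained with Adam
  (cross-entropy, batch 64, 15 epochs, learning rate 1e-3). Minibatches
  are drawn by a weighted random sampler with weight 1/(class count), so
  expected class frequencies are equal even for the 3-class head. The
  learning rate is set for a from-scratch linear head at desk scale:
  with ~1.5k training patches and 15 epochs the head sees only a few
  hundred Adam updates, an order of magnitude fewer than a full-scale
  transfer-learning run, and a fine-tuning-scale rate (1e-4) leaves it
  visibly under-converged.
- **Model selection** — after every epoch the patient-level binary
  MSI-vs-MSS AUROC on the validation fold is computed through the full
  aggregation path; the best epoch's weights are returned. Training is
  bitwise reproducible given the config seed.
- An `inception_v3_finetune` backbone name is reserved as an adapter
  hook for full-scale transfer-learning experiments; it raises
  `NotImplementedError` here.

Data preparation reproduces both stated balancing mechanisms: MSS
patches are randomly discarded once, at cohort construction, until the
two base classes have equal patch counts, and the weighted sampler then
maintains balance over the (possibly 3-class) training labels. Folds
are patient-level stratified k-folds (k=5) keyed on the sub-labels, so
every fold carries the same mix of sub-classes; patients are sorted by
id before splitting, making the partition invariant to input order. For
every comparison the baseline is retrained on byte-identical patch sets
and fold splits as its decomposed counterpart.

## Synthetic cohorts

The generator emulates the published cohort structure: 260 training and
100 test patients by default, MSI prevalence 15% (train) and 26%
(test), 20 patches per patient at 64×64 px RGB.

Genomic covariates:

- MSI SNP counts follow a truncated log-normal calibrated so the
  *truncated* median is exactly 1432 (σ = 1.1 on the log scale,
  truncated to [10, 17000]); MSS SNP counts are uniformly low (median
  60). Drawing ≥2000 MSI patients reproduces the median within 10%.
- CIMP-H occurs in 60% of MSI patients and 5% / 1% of MSS train / test
  patients; the remainder splits between CIMP-L and non-CIMP.
- CNV fractions: MSI on a tight log-normal with median 0.003 (about a
  quarter of MSI patients exceed the 0.005 decision point, so the CNV
  split is non-degenerate), MSS on a broad Beta(2.5, 5) centred well
  above it.

Every MSI patient carries a hidden morphological mode, A or B (50/50).
Coupling between a covariate and the mode is the fidelity ρ of that
feature. For threshold features (SNP, CNV) the covariate is drawn from
the side of its population median matching the mode with probability
(1+ρ)/2 by inverse-CDF side-sampling — the marginal distribution is
exactly preserved at every ρ, at ρ=1 the mode is a deterministic
function of the covariate's side, and at ρ=0 they are independent. For
the categorical CIMP feature the conditional rates are
P(CIMP-H | B) = 0.6 + 0.4ρ and P(CIMP-H | A) = 0.6 − 0.4ρ: the 60%
marginal is preserved at every ρ, and at ρ=1 the MSI-NON-CIMP-H
sub-class is pure mode A while CIMP-H remains a 5:1 mixture favouring
mode B. A fully deterministic CIMP↔mode map would force the marginal to
50% and was rejected in favour of the published 60%. Defaults are
ρ_SNP = ρ_CIMP = 1 and ρ_CNV = 0 — the coupling pattern the experiments
probe.

Patch morphology is a parametric proxy for H&E texture: elliptical
nuclei at Poisson-random positions on a noisy background. The two MSI
modes carry **orthogonal** signatures, with MSS between them on each
axis:

| phenotype | nuclei / 64 px² | radius (mean ± sd) | eccentricity | nucleus stain |
|---|---|---|---|---|
| MSS | 32 | 3.0 ± 0.45 | low | reference |
| MSI mode A | 32 | 3.0 ± 0.45 | low-mod | hematoxylin-shifted (+8, −4, +8 RGB) |
| MSI mode B | 58 | 4.6 ± 1.30 | low | reference |

Mode A matches MSS in density and size but has bluer, chromatin-dense
nuclei; mode B matches the MSS stain but is dense and pleomorphic. A
binary classifier must therefore pool two unrelated detectors into one
score, while the 3-class model gives each mode its own boundary — the
geometric mechanism by which decomposition helps. Per-patient "slide
effect" jitter (log-normal multipliers on nucleus count, σ=0.30, and
radius, σ=0.15; Gaussian per-channel shifts of background, σ=2, and
nucleus stain, σ=5) adds patient-level appearance noise that does not
average out over a patient's 20 patches, keeping patient-level AUROC
off the ceiling. These morphology constants were calibrated once so the
binary baseline sits mid-range (~0.8 patient AUROC) and then frozen;
the synthetic separability of the two MSI modes is a free design
parameter of the simulator, not an estimate of real tissue.

What the generator does *not* emulate: realistic H&E appearance, stain
normalization artefacts, within-patient genomic or morphological
heterogeneity, spatial patch correlation within a slide, or site-level
batch effects. Passing tests on these cohorts demonstrate the
*mechanism* — decomposition helps exactly when the decomposing feature
is coupled to morphology — not the accuracy attainable on real slides.

## Evaluation

AUROC is the pairwise concordance probability (ties ½, computed via the
trapezoidal ROC area); AP is the step-wise area under the
precision-recall curve; both are checked against brute-force oracles to
1e-12 in the tests. The F1 decision threshold sweeps all midpoints
between adjacent sorted unique scores plus {0, 1} and a below-minimum
sentinel (so the all-positive call is reachable when a score is exactly
0), breaking ties toward the lower threshold; confusion matrices at the
per-fold F1-optimal thresholds are averaged across folds. Model pairs
are compared with two-sided paired Student's t-tests on per-fold (or
per-seed-mean) metrics; a zero-variance difference vector is flagged as
degenerate rather than reported as p=0. Fold summaries use the normal
approximation mean ± 1.96·sd/√k for 95% CIs (a percentile option would
be a trivial extension; both sd and CI are emitted). MSI is the
positive class throughout.

The misclassification analysis assigns each patch (or patient) a
TP/FP/TN/FN outcome at a given threshold and summarizes the joined
patient-level molecular features per cell (SNP and CNV quartiles, CIMP
category counts). On coupled cohorts the baseline's false negatives
concentrate at low SNP counts — the signature that motivates
decomposition. Note the direction: false negatives here have a *lower*
median and narrower spread than true positives, because the
hard-to-classify mode occupies the lower half of the SNP distribution.

## Experiment protocol and problem sizes

The headline experiment (`run_experiment`) uses the default cohort (260
train / 100 test patients, 20 patches each, 64 px), 5 stratified folds
and 5 seeds: per seed and fold, a binary baseline and a 3-class
decomposed head are trained on identical data and both are scored on
the same test cohort; the paired test runs across per-seed mean AUROCs.
The combined-model experiment uses 3 seeds with the stacking protocol
above (fusion MLP: hidden 16, Adam lr 1e-3, 300 epochs, batch 64).
These sizes run in a few minutes each on one CPU and were chosen as the
smallest at which the patient-level comparisons are stable across
seeds.

## Known limitations

- The featurizer is not trained; on real histology, representation
  learning is a second mechanism by which sub-class supervision can
  help, and it is out of scope here.
- With a single latent mode axis, the SNP- and CIMP-decomposed models
  are redundant by construction, so fusion can only defend — not
  beat — the better constituent; demonstrating a fusion *gain* would
  require complementary latent structure.
- Best-epoch selection on small validation folds is upward-biased
  (max over 15 noisy AUROC draws); `best_val_auroc` should not be read
  as an unbiased performance estimate — held-out test metrics are the
  ones reported.
- Patients are i.i.d.; there is no slide, site or batch hierarchy.
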