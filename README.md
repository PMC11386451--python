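# bpsubtype

Biologically-primed patch classification for colorectal-cancer molecular
subtyping, with a synthetic histology cohort generator for controlled
experiments.

## The problem

Colorectal cancers are subtyped into microsatellite-instable (MSI) and
microsatellite-stable (MSS) tumors, a distinction that drives
immunotherapy decisions. Patch-level classifiers can recover this label
from H&E histology, but they treat MSI as one homogeneous class even
though MSI tumors are genomically heterogeneous — SNP burdens span three
orders of magnitude, and only ~60% of MSI tumors are CIMP-high. If that
genomic heterogeneity shows up in the tissue's appearance, a binary
classifier is forced to learn a single decision boundary around a
multi-modal class.

`bpsubtype` implements the class-decomposition remedy and the machinery
to test when it works:

- **Sub-labelling** — during training, MSI patients are split into two
  sub-classes by a genomic covariate: a threshold rule on SNP count
  (`s_i > t → MSI2`, else `MSI1`; strictly greater-than) or CNV fraction
  (default threshold 0.005), or a categorical rule on CIMP status
  (MSI-CIMP-H vs MSI-NON-CIMP-H, with CIMP-H MSS patients excluded from
  training). Inference uses images only.
- **Aggregation** — a patient's MSI score is the mean of per-patch MSI
  probabilities, `P_w(MSI) = Σᵢ F(xᵢ)/N`; for a 3-class model a patch's
  MSI probability is `max(p_MSI1, p_MSI2)`, taken per patch before the
  mean.
- **Fusion** — two decomposed models are combined patch-wise by an MLP
  over their concatenated six class probabilities, trained on
  out-of-fold predictions (stacking), with the constituents frozen.
- **Evaluation** — patient-level AUROC / average precision / F1 with
  fold-wise 95% CIs, paired t-tests between models trained on identical
  data, F1-optimal decision thresholds, confusion matrices, and a
  misclassification-versus-molecular-feature breakdown.
- **Synthetic cohorts** — because the interesting question is *when*
  decomposition helps, the generator draws patient cohorts (default 260
  train / 100 test, 15% / 26% MSI prevalence) whose genomic covariates
  match the published distributions (MSI SNP median 1432 on [10, 17000];
  CIMP-H in 60% of MSI, 5% / 1% of MSS train/test; CNV low in MSI,
  elevated and variable in MSS) and whose patch morphology carries a
  hidden two-mode structure within MSI. Each feature's coupling to that
  morphology is a dial ρ ∈ [0, 1]: ρ=1 for the SNP analogue makes
  decomposition informative, ρ=0 for the CNV analogue makes it a
  randomization control.

## Worked example

```python
from bpsubtype import ExperimentConfig, run_experiment
from bpsubtype.sublabels import snp_scheme

config = ExperimentConfig(scheme=snp_scheme(), seeds=[0])
result = run_experiment(config)
print("baseline AUROC per fold:", [round(a, 3) for a in result.baseline.auroc_per_fold])
print("decomposed AUROC per fold:", [round(a, 3) for a in result.bp.auroc_per_fold])
c = result.comparison
print(f"mean AUROC: baseline {c['mean_auroc_baseline']:.3f}, decomposed {c['mean_auroc_bp']:.3f}")
```

prints (about 20 s on one CPU):

```
baseline AUROC per fold: [0.795, 0.816, 0.82, 0.859, 0.825]
decomposed AUROC per fold: [0.866, 0.833, 0.853, 0.868, 0.791]
mean AUROC: baseline 0.823, decomposed 0.842
```

One simulated cohort (seed 0), five stratified folds: the binary
baseline and the 3-class SNP-decomposed model are trained per fold on
byte-identical patch sets, and every fold's models are scored on the
same 100-patient held-out test cohort. With full SNP–morphology coupling
the decomposed model wins on four folds of five here; across five seeds
the improvement is consistent (paired t-test across seed means, p <
0.05), while rerunning with `cnv_scheme()` (an uncoupled feature) shows
no systematic difference — the package's desk-scale reproduction of the
central claim.

Everything is also scriptable from the shell:

```
bpsubtype simulate --out cohort/ --seed 0
bpsubtype label --scheme snp --threshold 1200 --patients cohort/patients.csv --out sub.csv
bpsubtype folds --patients cohort/patients.csv --sublabels sub.csv --k 5 --seed 0 --out folds.csv
bpsubtype train --patches cohort/ --sublabels sub.csv --folds folds.csv --fold 0 --out model/
bpsubtype predict --model model/ --patches cohort/ --out preds.csv
bpsubtype aggregate --preds preds.csv --out scores.csv
```

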