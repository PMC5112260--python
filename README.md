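# pilvq

Prototype-based classification of cognitive profiles with fMRI-derived
**privileged information**.

## The problem

Mild Cognitive Impairment (MCI), the prodromal stage of Alzheimer's
disease, shows up both in cognitive test scores and in functional brain
imaging. Imaging is far more informative but expensive, and many older
patients cannot be scanned at all. `pilvq` implements a classification
methodology for exactly this asymmetry: a classifier that **predicts from
four cognitive scores alone** — working memory (*n*<sub>dots</sub>),
inhibition (*t*<sub>delay</sub>), divided attention (*t*<sub>disp_d</sub>)
and selective attention (*t*<sub>disp_s</sub>) — while **fMRI features,
available only for a training subset, shape its distance metric during
training**.

The package is aimed at methods researchers in neuroimaging machine
learning: every stage is exposed as a scikit-learn-style estimator or a
plain function, and a seeded synthetic-cohort generator stands in for the
original (non-deposited) clinical cohort so the whole pipeline is testable
end to end.

## The method

**GMLVQ.** The core classifier is Generalized Matrix Learning Vector
Quantization: one prototype **w**<sub>±</sub> per class and an adaptive
full metric tensor Λ = Ω<sup>T</sup>Ω with distance

> d<sub>Λ</sub>(**x**, **w**) = (**x** − **w**)<sup>T</sup> Λ (**x** − **w**),

trained online by steepest descent on φ(μ) with
μ = (d<sup>+</sup> − d<sup>−</sup>)/(d<sup>+</sup> + d<sup>−</sup>),
Λ trace-normalized after every step. The diagonal of Λ ranks feature
relevance; off-diagonals expose pairwise feature interplay.

**Privileged information.** For training subjects with imaging, a GMLVQ is
first trained in the privileged (fMRI-feature) space, giving a metric
Λ<sup>\*</sup>. Subject pairs that are close under Λ<sup>\*</sup> and share
a label become *similar* constraints; distant different-label pairs become
*dissimilar* constraints. Information-Theoretic Metric Learning (ITML,
LogDet-divergence Bregman projections) then pulls the cognitive-space
metric toward satisfying these constraints, and the prototypes are
retrained under the fused metric. Prediction needs cognitive scores only.

**fMRI features.** Per subject, ROI and session (pre/post training):
percent signal change (PSC) contrasts structured vs. random stimulus
blocks; voxel-level Pearson correlation graphs are reduced through
Gaussian kernel bases built either by k-means on voxel positions (spatial
grouping, SGF) or by consensus clustering of per-subject connectivity
partitions (functional grouping, FGF), and a 2D-LDA bilinear discriminant
f = **a**<sup>T</sup>X̃**b** turns each reduced graph into a scalar.
I = (**ab**<sup>T</sup> + **ba**<sup>T</sup>)/2 gives per-edge
discriminative importance.

**Evaluation.** Repeated stratified splits; per split, class imbalance is
handled by an ensemble of classifiers each trained on the full minority
class plus an equal-size majority downsample, combined by majority vote.
The headline metric is the macroaveraged mean absolute error (MMAE; for
binary labels, 1 − balanced accuracy). Two ensembles trained with
different privileged families can be merged per test point via normalized
metric-tensor confidences.

## Worked example

```python
from pilvq import (ExperimentConfig, default_config, run_experiment,
                   simulate_cohort, summarize_tables)

cohort = simulate_cohort(default_config(seed=0))   # 13 patients / 47 controls,
                                                   # 34 with imaging
results = [
    run_experiment(cohort, ExperimentConfig(model_name=name, n_splits=10,
                                            n_downsamples=10, epochs=60,
                                            seed=0, collect_relevance=False))
    for name in ("M-CD", "M+-CD-PSC", "M-PSC")
]
print(summarize_tables(results).round(3).to_string(index=False))
```

prints

```
    model  mean   std  median   q25   q75  p_value  median_reduction_pct   TPR   TNR
     M-CD 0.329 0.116   0.295 0.241 0.420      NaN                   NaN 0.650 0.693
M+-CD-PSC 0.363 0.094   0.357 0.304 0.438    0.062               -21.212 0.575 0.700
    M-PSC 0.000 0.000   0.000 0.000 0.000    0.002               100.000 1.000 1.000
```

Reading the table: `M-CD` is the cognitive-only baseline (median MMAE
0.295 over 10 splits; 0.5 is chance). `M-PSC`, which sees the synthetic
cohort's strongly informative imaging features directly, separates the
classes perfectly — the lower bound on achievable error. `M+-CD-PSC`
predicts from cognitive scores alone with imaging as privileged
information; on this cohort and at this small split count it stays near
the baseline (the paired Wilcoxon p-value against the baseline is 0.062),
and across larger experiments it sits between the two extremes. The
`median_reduction_pct` column is the relative change of each model's
median MMAE against the first (baseline) row.

A thin CLI wraps the same pipeline:

```bash
pilvq simulate --seed 0 --out cohort/
pilvq evaluate --model M-CD --n-splits 10 --n-downsamples 10 --out run/
```

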