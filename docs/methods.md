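# Methods

This note documents the models implemented in `pilvq`, the choices made
where the methodology leaves details open, what the synthetic cohort
generator does and does not emulate, and known limitations.

## Classifier

GMLVQ represents each class by a single prototype in the (z-scored)
feature space and measures distance through an adaptive metric tensor
Λ = ΩᵀΩ, which is positive semi-definite by construction. Training is
online steepest descent on the per-sample cost φ(μ), with
μ = (d⁺ − d⁻)/(d⁺ + d⁻) the relative difference between the distances to
the closest correct-class and closest wrong-class prototype, and φ the
identity. After every learning step Λ is renormalized to unit trace,
fixing the otherwise arbitrary global scale of the metric; prediction is
winner-takes-all and invariant to any positive rescaling of Λ.

Optimizer constants (not dictated by the methodology; standard GMLVQ
practice, exposed as estimator parameters): prototype learning rate 0.01,
metric learning rate 0.001, both decaying linearly to 10% over the run;
300 epochs by default; Ω initialized to I/√m; prototypes initialized as
the mean of a random half of each class's training points. Features are
z-scored inside the model with training-set statistics because the
cognitive scores mix units (dots vs. milliseconds). Exact distance ties at
prediction go to the smaller class label, with a warning. The analytic
gradients are verified against finite differences in the test suite.

## Privileged-information fusion

The fusion is a five-stage procedure: (1) train GMLVQ in the privileged
space → Λ*; (2) train a baseline GMLVQ in the original space → Λ and
prototypes; (3) tag subject pairs using privileged distances under Λ*,
with the similar/dissimilar thresholds l*, u* taken as the a*-th/b*-th
percentiles of the pairwise distance distribution (similar additionally
requires equal labels, dissimilar different labels); (4) run ITML —
LogDet-divergence Bregman projections with slack γ = 1, up to 1000 sweeps,
stopping when the largest dual update falls below 10⁻³ — with prior Λ and
distance targets l, u set to the a-th/b-th percentiles of the
original-space pairwise distances under Λ; (5) trace-normalize the fused
metric and retrain the prototypes only under it. The design was genuinely
open in two places: how the original-space percentile bounds enter (they
are the natural ITML targets, which is where we put them) and whether the
fusion alternates metric and prototype updates (we use the staged variant;
it is deterministic and separable, and each stage is testable in
isolation). Rank-one Bregman updates keep every ITML iterate PSD, which
the suite checks on random instances.

The four percentile bounds default to (a = a* = 10, b = b* = 90), the
midpoints of the conventional tuning grids {5, 10, 15} × {85, 90, 95}. A
grid search over those values by cross-validation on a single split
(`tune_percentile_bounds`) is provided but off by default: at desk-scale
experiment sizes an 81-point grid of ensemble trainings costs far more
than the residual sensitivity to the bounds warrants.

## fMRI features

**PSC** is implemented with the denominator as the *sum* of the two
condition means, (m_s − m_r)/(m_s + m_r) averaged over voxels; a
`denominator="mean"` flag gives the factor-2 variant in which the
denominator is the average response. PSC is scale-free by construction.

**Graph features.** The connectivity graph is the voxel-by-voxel Pearson
correlation matrix over all volumes. Dimensionality is reduced by a
congruence X̃ = PᵀXP with P[i,k] the density of Gaussian kernel k at voxel
i. Spatial grouping builds kernels by k-means on voxel positions (50
restarts, fixed seed; 8-kernel bilateral ROIs are clustered per hemisphere,
4 each side); kernel covariances are the within-cluster position
covariances, ridge-regularized by 10⁻⁶·trace/3 (unit mm² if degenerate),
since two-voxel clusters give singular covariances. Functional grouping
clusters each subject's voxels by average-linkage on dissimilarity 1 − G
cut at K, accumulates a co-association matrix (fraction of subjects
co-clustering a voxel pair) and clusters 1 − co-association the same way;
the consensus-clustering literature it follows does not fix an algorithm,
so average linkage is used at both levels for determinism.

**2D-LDA.** The bilinear discriminant maximizes
J(a,b) = (aᵀ(M₂−M₁)b)² / Σₙ (aᵀ(Xₙ−M_c)b)², implemented literally as
squared scalar bilinear forms. With one vector fixed the problem in the
other is an exact generalized symmetric eigenproblem, so each alternating
half-step is an exact maximizer and the J trace is monotone by
construction (a numerically stalled step terminates the iteration rather
than accept a decrease). Defaults: b initialized uniform, tolerance 10⁻⁸
on the relative change of J, 100 iterations maximum. The bilinear feature
is invariant under a joint sign flip of (a, b); the observable ambiguity
is their relative sign, which is fixed by flipping b alone so the
patient-class mean feature is the larger one. The edge-importance matrix
I = (abᵀ + baᵀ)/2 is unit-scale (a, b are unit vectors): it encodes
*where* discriminative structure lies, not how strong it is, so pre/post
importance shifts reflect relocation of discriminative edges rather than
global effect growth.

## Evaluation design

Split protocols fix the per-class training counts (imaging cohort: 6
patients + 17 controls of 9/25; full cohort: 9 + 33 of 13/47) and, for the
full-cohort protocol, draw training subjects proportionally from the
with-/without-imaging subgroups so both sides of a split preserve modality
balance. Class imbalance is handled by downsampling ensembles: every
member sees the full minority-class training portion plus an equal-size
draw of the majority class; majority voting with ties resolved toward the
patient class (the clinically conservative choice; logged). MMAE is the
standard macroaveraged mean absolute error with classes coded 1..C — the
printed formula in the source material garbles its indices, so the verbal
definition (per-class mean absolute error averaged over classes) is
implemented; for binary labels it equals 1 − balanced accuracy. Model
comparisons over identical splits use the two-sided paired Wilcoxon
signed-rank test (the source tables do not name their test; a paired
nonparametric test matches the paired design). When two ensembles are
combined, disagreements are resolved toward the ensemble whose voting
members are on average closer to their winning prototype under
eigenvalue-normalized metric tensors, which makes distances comparable
across independently scaled classifiers.

## Relevance analysis

Splits whose N_b-th best ensemble member (default N_b = 15) has error
above E_max = 25% are discarded; all members of surviving splits are
pooled. "Error" here is the member's balanced training error — the
selection rule must not touch test data (a flag allows the alternative).
The diagonal histogram counts, per feature, pooled diagonal elements above
the pooled 90th percentile; ties *at* the percentile count unless the pool
is flat, so a single feature saturating the top decile is credited rather
than erased by its own ties. Off-diagonal interplay uses two one-sided
signed-rank tests per pair (median above/below zero) at α = 0.05, without
multiplicity correction by default (Benjamini–Hochberg available). The
between-class screen tests each raw feature with one-sided rank-sum tests
(the groups are unpaired and of unequal size, so a signed-rank test is not
applicable) and combines per-feature directions into pairwise
positive/negative/insignificant verdicts. Pre/post edge-importance shifts
are tested pairwise by split with one-sided signed-rank tests on the
post − pre differences.

**Known statistical limitation.** Pooled ensemble members are trained on
overlapping subsets of one fixed cohort and are strongly dependent, so
the signed-rank interplay tests on pooled member matrices are
anticonservative: on null cohorts they flag pairs far above the nominal α,
because they detect the cohort's accidental between-class structure. This
mirrors the source procedure and is retained as specified; the
between-class screen, whose rank-sum tests are correctly calibrated across
independent cohorts, is the module's calibrated null check and is what the
type-I acceptance check exercises.

## Synthetic cohort generator

The generator emulates the study conditions: 13 patients / 47 controls
with cognitive scores, 34 subjects (9 patients, 25 controls) additionally
imaged in three ROIs of 126/82/32 voxels, two sessions, 30 structured +
30 random volumes in alternating 5-volume blocks. Cognitive scores are
class-conditional Gaussians with a shared within-class covariance
(SDs 1.2 dots, 35/32/30 ms; working memory–inhibition correlation 0.3,
attention–attention 0.2). Class means differ primarily along divided
attention (+1.5 within-class SD for patients — with only 13 patients the
sampling error of a per-feature separation is ~0.3–0.4 SD, so a clearly
dominant primary coordinate is required for relevance recovery to be
identifiable at all); secondary shifts of ~0.3 SD carry the clinical sign
structure (patients hold fewer dots, tolerate shorter stop delays, need
slightly longer selective-attention displays). Voxels sit in K Gaussian
blobs on a mm grid (so k-means grouping is recoverable); time series are
baseline 100 + a condition offset on structured volumes (default: +6 for
patients post-training in the frontal ROI, +3 cerebellar — an activation
increase after training specific to patients) + unit-variance latent
cluster signals carrying planted inter-cluster correlations (default: a
frontal cluster pair correlated 0.7 in patients vs 0.1 in controls before
training, converging to 0.45/0.35 after — a connectivity difference that
training mitigates) + white noise (SD 1). All randomness derives from one
seed through named substreams, so cohorts are bit-reproducible and
per-subject generation is order-independent.

What the generator does **not** emulate: haemodynamic response dynamics,
scanner noise spectra and drift, motion, spatial autocorrelation beyond
cluster membership, and any realistic calibration of the cognitive-score
distributions (the study reports none). Passing tests therefore show that
the pipeline recovers structure it is designed to detect under idealized
noise, not that it would perform comparably on real BOLD data.

## Problem sizes

Default experiment scale is 50 splits × 100 downsamples, matching the
study design. The test suite and the acceptance script run desk-scale
configurations chosen as the package's own CI sizes: ordering experiments
at 20 splits × 20 downsamples with 60-epoch members, calibration on five
independent null cohorts at 8 splits × 8 members, recovery rates over
50 seeded fits (100 epochs) and 20-seed shift detections. The null
calibration pools splits over several independently generated cohorts
because a single finite cohort carries accidental class differences that
all of its splits share; the pooled median is the quantity with a stable
chance level.
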