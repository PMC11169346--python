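# Methods

`morphsev` reimplements, as a tested library, an analysis pipeline for
predicting severe post-stroke aphasia from ordinal brain-morphometry volumes,
explaining the predictions with saliency attribution, and subtyping
individuals by consensus clustering of their saliency maps.  This note
documents the models, the synthetic study conditions, the numerical choices,
and the limits of what the tests demonstrate.

## Data representation

Each subject is a 3D grid of ordinal tissue codes on a shared voxel lattice:
0 background, 1 CSF, 2 gray matter, 3 white matter, 4 lesion (the lesion code
supersedes tissue).  For model input the codes are mapped affinely to
[-1, 1] (code/2 − 1).  The representation stands in for voxelwise regional
tissue volume: atrophy appears as gray matter replaced by CSF, so *total*
atrophy is a count, while its *spatial arrangement* is a pattern only a
spatially aware model can exploit.

Preprocessing operations on these grids are deterministic: merging tissue and
lesion masks; simplified enantiomorphic healing (voxels inside the dilated
lesion mask take the value at their midsagittal mirror position); modal
downsampling (each factor³ block becomes its modal code, ties broken by the
larger code — lesion > WM > GM > CSF > background — which is the natural
ordinal-preserving reduction and deterministic); cohort-wide cropping of
planes that are background in every subject; min-max scaling.  The midline is
the plane between columns n/2−1 and n/2 of the left/right axis; grids are
generated with an even first axis.

## Synthetic cohort

The generator defines the study conditions under which every downstream stage
is exercised, without any data download:

* **Template.** A deterministic, mirror-symmetric ellipsoidal brain (WM core,
  GM shell, CSF margin and ventricles) given the grid shape (default 24×28×24
  at a nominal 8 mm).  Determinism isolates all randomness in the lesion,
  atrophy, and outcome draws; each subject has an independent stream seeded
  by (cohort seed, subject index), so generation is reproducible and
  parallel-safe.
* **Lesions.** Connected regions grown by randomized flood fill from a
  lateral left fronto-temporal seed, confined to left-hemisphere brain
  voxels, with size uniform over a configurable range (default 40–400
  voxels).  This emulates the compact territory of middle-cerebral-artery
  strokes; it does not model vascular anatomy.
* **Atrophy motifs.** Exactly `atrophy_voxels` GM voxels (default 30) are
  converted to CSF per subject.  A *clustered* motif takes the nearest GM
  voxels around a random center (anywhere in GM, including the right
  hemisphere, so extralesional signal exists); a *dispersed* motif scatters
  the same count uniformly over GM.  Totals are therefore matched exactly
  across motifs — only arrangement differs — which is the planted effect the
  CNN-vs-SVM comparison is designed to detect.
* **Outcome.** A WAB-AQ-like score,
  `wab = clip(100 − a·lesion_fraction − b·[motif harmful] + N(0, σ), 0, 100)`,
  binned at 25/50/75 into very severe / severe / moderate / mild; severe
  means wab ≤ 50.  The defaults (a = 850 per unit lesion fraction, b = 26,
  σ = 12 points) were calibrated once by simulation so that ≈35 % of subjects
  are severe and all four categories occur, then frozen.  The linear-Gaussian
  form is the simplest mechanism reproducing the larger-lesion/higher-severity
  association.

What the generator does **not** emulate: MRI contrast, registration error,
scanner noise, realistic cortical geometry, or correlated atrophy networks.
Tests passing on this cohort show the pipeline's machinery is correct and
that its comparative claims hold under planted ground truth; they do not
certify clinical performance.

## Cross-validation plan

One `PartitionPlan` object carries all fold assignments and is consumed by
every model, making across-repeat comparisons paired by construction.
Defaults: 20 repeats × 6 outer folds (testing) × 8 inner folds (tuning),
stratified by the four granular categories; each outer training set is also
resplit 70/30 (stratified) into train/validation for CNN retraining.  Within
each stratum, folds receive floor(n/k) or floor(n/k)+1 members, with the
remainders dealt to the folds with the smallest running totals; this
guarantees ≤1 per-stratum imbalance and overall outer-fold sizes of 38–39 at
N = 231 (inner held-out folds 24–25, validation 58).  Repeat r uses seed
`seed + r`.  Singleton strata cannot be split for validation and stay on the
training side.  The plan serializes to JSON and is content-hashed so
independent runs can assert they consumed byte-identical partitions.

## CNN

A single-channel 3D VGG-family classifier: blocks of 3×3×3 "same"
convolutions with ReLU, each block followed by 2×2×2 max pooling (ceil
mode), then three fully connected layers of widths (2C, C, 2) where C is the
last convolutional channel count, with batch normalization after FC1 and
dropout immediately after.  Four frozen complexity levels span the family
(4–5 blocks, 1–4 convolutions per block, 8–128 channels); the tuning grid
crosses complexity with dropout {0.6, 0.7, 0.8}, L2 {0.001, 0.01}, and
learning rate, selected by smallest mean inner-fold validation loss (ties to
lower complexity, then lower rate).

Training minimizes softmax cross-entropy weighted by inverse class
frequencies (w_c = N/(2 n_c)) plus an L2 penalty on weights, using momentum
SGD (momentum 0.9) under a cosine-annealing schedule with warm restarts:
cycles of 50, 100, 200, … epochs, annealing from lr0 to a floor of 1e-10
within each cycle.  Early stopping monitors the validation weighted loss
(default patience 100) and the best-validation weights are restored.  If the
training set is smaller than the batch size (128), a single full batch is
used.  The engine is plain numpy with explicit backpropagation; gradients are
verified against central differences in the tests.

Desk-scale profiles used by the tests train 2-block networks at learning
rates around 1e-2 for a few hundred epochs; the rate differs from the study
grid (≈1e-4) because the optimizer and problem size differ, and it is
configuration, not a constant.

## SVM

Class-weighted support vector classification (libsvm's SMO) on flattened
scaled volumes — or interchangeably on CNN penultimate features or flattened
saliency maps.  Kernels linear and RBF are fitted as *separate* models (the
kernel is never tuned).  The RBF width is a kernel scale s with
K(x,y) = exp(−‖x−y‖²/s²).  Hyperparameters (cost 1e-3–2e4, kernel scale
1e-3–1e3) are drawn from 300 logarithmically spaced bins by random search and
scored by mean inner-fold inverse-frequency-weighted hinge loss; optional PCA
or PCA-then-ICA reduction (1–75 components, tuned) is refitted inside every
fold on training rows only.  Probabilities come from a Platt-style sigmoid
fitted on training-fold decision values with regularized targets; the slope
is constrained nonnegative so the probability is monotone in the decision
value.

## Fusion

* **Weighted averaging** of severe-class probabilities, p = w·p_cnn +
  (1−w)·p_svm over a grid of 101 weights (F1 as a function of w is piecewise
  constant, so the grid argmax is exact at these cohort sizes).
* **LDA stacking**: a two-feature Gaussian linear discriminant trained on a
  stratified random half of each outer test fold's (p_cnn, p_svm) pairs and
  evaluated on the other half; the regularizer γ (500 linearly spaced values
  in [0, 1]) shrinks the pooled covariance toward its diagonal,
  Σ_γ = (1−γ)Σ + γ·diag(Σ).
* **Chaining**: SVMs trained on CNN features or saliency maps reuse the SVM
  module unchanged on a different table.

Sweep maxima are explicitly optimistic best-case bounds, reported as such.

## Saliency

* **Grad-CAM++** on the last convolutional block's ReLU activations, with
  the closed-form second-order weights for an exponential-of-score target:
  α = g²/(2g² + ΣA·g³) elementwise (g the score gradient), channel weight
  w_k = Σ α·ReLU(g), map = ReLU(Σ w_k A_k), trilinearly upsampled to the
  input grid.  On a GAP-linear head with nonnegative class weights this
  reduces to the class-activation map, which the tests use as a closed-form
  oracle.
* **Deep SHAP** via DeepLIFT rescale multipliers propagated through the
  network against a training background set.  Affine layers propagate
  multipliers like gradients; ReLU uses Δout/Δin; max pooling uses an exact
  rule attributing each window's change in maximum to a single carrying
  input, so completeness (attributions sum to score(x) − mean background
  score) holds end to end up to float precision and is asserted directly.
* **Kernel SHAP** for black-box models: Shapley-kernel weighted regression
  over coalitions, with absent features imputed from the k nearest neighbors
  of the explained sample (k = 10 % of the dataset).  Small feature counts
  are enumerated exactly; otherwise coalitions are Monte-Carlo sampled in
  antithetic pairs (coalition + complement) with the kernel encoded in the
  size distribution.
* Maps are rectified (negatives zeroed) and normalized to sum to 1 before
  group analysis; an all-zero map stays zero and is flagged.

ROI analysis partitions the left hemisphere into lesion, perilesional
(lesion dilated by 2 voxels — 16 mm at 8 mm resolution — with
26-connectivity, minus the lesion), and extralesional tissue, plus their
midline-reflection homologs clipped to the right hemisphere; the six masks
are pairwise disjoint and the left three tile the left hemisphere's brain
voxels exactly.  Group statistics are two-sample t-tests on per-subject mean
normalized saliency within each ROI, intended for correctly predicted
subjects.  Saliency is reported for the mean-performing repeat (F1 closest
to the across-repeat mean, ties to the earlier repeat).

A note on the η² similarity used throughout: with the definition
η² = 1 − Σ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σ[(aᵢ−M̄)² + (bᵢ−M̄)²]
(mᵢ the pointwise midpoint, M̄ its grand mean), the numerator equals
½‖a−b‖² and num − den = −½Σ(aᵢ+bᵢ−2M̄)², so the coefficient is bounded in
[0, 1]; unrelated sparse maps sit near 0.5.  All cross-method comparisons
here are directional and unaffected by the floor.

## Consensus subtyping

Saliency maps (severe and nonsevere predictions clustered separately) are
repeatedly clustered on random 60 % subsets of voxels with η²-distance
k-means (k-means++ seeding under the same distance; mean centroids are a
principled surrogate because the η² numerator is half the squared Euclidean
distance; descent is not guaranteed, so the best labels over a 100-iteration
cap are kept; empty clusters reseed from the farthest point; best of
`replicates` restarts).  Because subsampling is over voxels, every subject
pair appears in every iteration and the consensus matrix is the plain
co-clustering proportion.

Model-order selection: solutions whose consensus distribution fails to
reject unimodality under a dip test (α = 0.05) are excluded — a unimodal
consensus means pairs are neither consistently together nor consistently
apart; the remaining solutions are ranked by the proportion of ambiguously
clustered pairs (PAC; entries strictly inside (0.1, 0.9); threshold 0.1),
and the largest qualifying k is selected.  If nothing qualifies, the
minimum-PAC k is returned with a warning.  Clusters and exemplars are then
extracted by affinity propagation on the consensus matrix (damping 0.7),
with the preference bisected until the cluster count matches the selected k
(nearest achievable otherwise).

The dip statistic is computed from the greatest-convex-minorant /
least-concave-majorant characterization of unimodal fits to the empirical
staircase (minimum over modal positions of half the larger one-sided maximal
deviation); on perfectly evenly spaced data it attains the known 1/(2n)
floor.  P-values are Monte-Carlo calibrated under the uniform null with the
same statistic and sample size, so the test is exactly calibrated by
construction; consensus samples larger than 1000 values are thinned before
the bootstrap.

Reference compute settings are 1000 voxel subsamples × 250 k-means restarts
over k = 3…30; the test and example profiles use reduced settings (tens of
subsamples, k up to 8) which already separate planted archetypes perfectly.

## Evaluation

Metrics are computed from predictions concatenated across outer folds:
precision, recall (= severe-class accuracy), nonsevere accuracy, balanced
accuracy (mean of class accuracies), and F1 (harmonic mean of precision and
recall, 0 when no positive predictions), aggregated as median and range
across repeats.  The permutation test rebuilds the full modelling procedure
under label permutation, with p = (#{null ≥ observed} + 1)/(m + 1); paired
model comparisons are paired t-tests across repeats with Cohen's
d = mean(diff)/sd(diff) (zero-variance differences are flagged degenerate).
Topic decoding correlates a saliency map (lesion voxels removed) with each
user-supplied topic map and retains topics with r > 0.2 and Bonferroni
corrected p < 1e-4, using the t-approximation with n = included voxels — a
caveat: voxelwise spatial autocorrelation is not modelled, so decoding
p-values are optimistic on real data.

## Problem sizes used by the tests

The test suite runs study-shaped but desk-scale problems on one CPU: the
spatial-sensitivity experiment uses 200 subjects on 16³ grids with 40
atrophied voxels (~6 % of template GM), a 2-block CNN (8/16 channels, 250
epochs), and three seeds; subtype recovery uses 90 maps from 3 archetypes
with 40 subsamples × 8 restarts over k = 3…8; the end-to-end smoke run uses
48 subjects on 12³ grids with 2 repeats of 2×2 nested folds.  The full-scale
settings (231 subjects, 20×6×8 folds, 800 epochs, 4-level grid, 1000×250
consensus) remain the configuration defaults or documented reference values.

## Known limitations

* The CNN engine is CPU-bound numpy; it is exact but not fast, and the
  provided architecture grid at full scale is cluster-sized work.
* Hinge-loss tuning, Platt calibration, the stratified 70/30 resplit, the
  perilesional radius, and the AP preference bisection are reasonable
  defaults where the procedure leaves details open; all are configuration.
* The dip p-value is Monte-Carlo (resolution 1/(n_boot+1)).
* Real-data mode accepts pre-registered NIfTI tissue+lesion grids and a
  phenotype table; registration, segmentation, and topic-map generation are
  out of scope.
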