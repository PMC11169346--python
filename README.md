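# morphsev

Severe post-stroke aphasia affects roughly a third of chronic stroke
survivors and is the strongest determinant of rehabilitation need.  Lesion
size and location explain much of the variance in severity, but tissue
integrity *beyond* the lesion — regional atrophy patterns in spared cortex —
carries additional predictive signal that voxelwise-blind models cannot see.
`morphsev` is a tested Python implementation of an analysis pipeline built
around that idea, for researchers working with volumetric morphometry of
stroke cohorts:

1. **Representation.** Each subject is a 3D grid of ordinal tissue codes
   (background 0, CSF 1, GM 2, WM 3, lesion 4), scaled to [−1, 1] for
   modelling.  Deterministic voxel operations cover lesion merging,
   simplified enantiomorphic healing, modal downsampling, cohort-wide
   cropping, and scaling (NIfTI in/out via nibabel).
2. **Prediction.** A 3D VGG-family CNN (numpy engine with explicit
   backpropagation, class-weighted cross-entropy, cosine-annealing warm
   restarts, early stopping) and class-weighted SVMs (linear and RBF, with
   optional PCA/ICA reduction folded into cross-validation) are trained and
   compared on one shared, preallocated, repeated nested stratified
   cross-validation plan — 20 repeats × 6 outer × 8 inner folds by default,
   stratified by the four WAB-R severity categories — so model comparisons
   are paired across repeats.  Binary target: severe aphasia, WAB-AQ ≤ 50.
3. **Fusion.** Weighted probability averaging over a weight sweep,
   regularized-LDA stacking on half-split test folds (covariance shrunk
   toward its diagonal, Σ_γ = (1−γ)Σ + γ·diag Σ), and chained SVMs on CNN
   features or saliency maps.
4. **Explanation.** Grad-CAM++ for the CNN (closed-form second-order channel
   weights), Deep SHAP (DeepLIFT-rescale with exact max-pool attribution, so
   completeness holds to float precision), and kernel SHAP for the SVM
   (k-nearest-neighbor conditional imputation, antithetic coalition
   sampling); ROI statistics over lesion / perilesional / extralesional
   masks and their midline homologs.
5. **Subtyping.** Consensus clustering of saliency maps: η²-distance k-means
   on repeated 60 % voxel subsamples, dip-test screening of consensus
   distributions, model-order selection by the proportion of ambiguously
   clustered pairs (PAC), and affinity-propagation extraction of clusters
   with exemplar subjects; exemplars can be decoded against user-supplied
   topic maps by thresholded Pearson correlation.

A built-in synthetic-cohort generator makes the whole pipeline testable with
no downloads: left-hemisphere lesions grown on a mirror-symmetric tissue
template, planted gray-matter atrophy motifs **matched on total atrophy but
differing in spatial arrangement** (clustered vs dispersed), and a WAB-AQ-like
outcome binned at 25/50/75 with ≈35 % severe subjects.  Matched totals mean
any purely additive model is blind to the motif — exactly the planted effect
the CNN-vs-SVM comparison is designed to detect.  Real-data mode accepts a
directory of pre-registered NIfTI volumes plus a phenotype CSV.

The core similarity used for subtyping is the η² coefficient
(1 = identical maps):

    η²(a, b) = 1 − Σᵢ[(aᵢ−mᵢ)² + (bᵢ−mᵢ)²] / Σᵢ[(aᵢ−M̄)² + (bᵢ−M̄)²],
    mᵢ = (aᵢ+bᵢ)/2,  M̄ = mean(m)

whose complement 1 − η² is the k-means distance.

## Worked example

A desk-scale end-to-end run — synthesize 48 subjects on a 12³ grid with
motif-driven labels, train the CNN and a linear SVM on an identical 2×(2,2)
nested plan, fuse, and report:

```python
from morphsev.partitions import PartitionConfig
from morphsev.pipeline import ExperimentConfig, run_experiment
from morphsev.synthetic import SyntheticCohortConfig

cfg = ExperimentConfig(
    cohort=SyntheticCohortConfig(
        n_subjects=48, grid_shape=(12, 12, 12),
        lesion_volume_range=(8, 40), atrophy_voxels=20,
        outcome_coefficients=(0.0, 60.0, 0.0),  # labels driven by the motif
        seed=0,
    ),
    partition=PartitionConfig(n_repeats=2, n_outer=2, n_inner=2, seed=0),
    cnn_blocks=((1, 8), (1, 8)), cnn_epochs=60, cnn_lr0=0.01,
    svm_variants=("linear",), svm_search_draws=2,
    out_dir="example_out", seed=0,
)
result = run_experiment(cfg)
print(result.summary.round(3))
```

Output (metrics are medians and ranges over the 2 repeats of
concatenated-outer-fold predictions):

```
                               median    min    max
model      metric
cnn        precision            0.564  0.462  0.667
           recall               0.304  0.087  0.522
           severe_accuracy      0.304  0.087  0.522
           nonsevere_accuracy   0.700  0.440  0.960
           balanced_accuracy    0.502  0.481  0.523
           f1                   0.322  0.154  0.490
svm_linear precision            0.439  0.357  0.520
           recall               0.391  0.217  0.565
           severe_accuracy      0.391  0.217  0.565
           nonsevere_accuracy   0.580  0.520  0.640
           balanced_accuracy    0.486  0.429  0.543
           f1                   0.406  0.270  0.542
```

Numbers regenerate exactly from the config and seed.  The reading: with
motif-driven labels and matched atrophy totals, the *linear SVM sits at
chance by design* (balanced accuracy ≈ 0.49 — no single voxel carries
signal), and at this smoke scale (48 subjects, 60 epochs) the CNN has not
yet learned the spatial motif either (≈ 0.50).  The properly powered version
of the same experiment — 200 subjects, 250 epochs, three seeds — runs in the
test suite and yields CNN balanced accuracies of 0.96 / 0.75 / 0.78 against
a still-chance-level SVM: the spatial arrangement of atrophy, not its total,
is what the convolutional model detects.

The `morphsev` CLI exposes the same stages
(`simulate`, `preprocess`, `plan`, `train-cnn`, `train-svm`, `fuse`,
`saliency`, `subtype`, `decode`, `report`, `run-all`):

```bash
morphsev simulate --out cohort/ --n-subjects 60 --grid 12 --seed 1
morphsev plan --cohort cohort/ --out plan.json --repeats 2 --outer 6 --inner 8
```

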