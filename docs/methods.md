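# Methods

This note documents the models, conventions and design choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and the
known limitations.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic study material

**Lesion renderer.**  A lesion is an ellipse in polar form
`r(θ) = ab / √((b cosθ)² + (a sinθ)²)` with semi-axis ratio `eccentricity`,
plus a sinusoidal radial perturbation (`border_waviness` = amplitude px,
frequency cycles) and a one-sided radial inflation of the upper half by
`(1 + asymmetry_coeff)`.  These three knobs map directly onto the A
(asymmetry) and B (border) of the clinical ABCD rule, so the geometric
features can be validated against known settings.  Colour variegation is a
set of palette-coloured blobs 0.14–0.24 of the lesion radius — deliberately
larger than the hair detector's structuring elements so that pigment
variegation and hair-scale structure remain distinguishable.  Pigment texture
and skin micro-noise are *spatially correlated* fields (Gaussian-smoothed
white noise, smoothing σ 2.5 px and 1.0 px, rescaled to the requested
per-pixel standard deviation in gray levels); uncorrelated per-pixel noise is
sensor-like, not tissue-like, and would saturate any morphological line
detector.  Hair is rendered as dark anti-aliased quadratic Bézier strokes
1–3 px wide; the exact blended footprint is returned as a mask, and hair uses
an independent random substream so the underlying lesion render is bit-
identical with and without hair.

**Table generator.**  The informative block is multivariate normal with unit
variances, equicorrelation `block_corr`, and a between-class mean shift of
`effect_size` standard deviations; remaining features are standard normal in
both classes.  Class counts are exact.  Defaults (160/40) mirror the scale of
a small dermoscopy collection with imbalance ratio 4.00.

**What the generators do not emulate:** dermoscopic structures (networks,
streaks, blue-white veil), illumination gradients, rulers/ink, heavy-tailed
or mixed-type feature distributions, and label noise.  Tests passing on this
material show the pipeline's operators are correct and well-calibrated under
controlled conditions; they do not certify performance on real dermoscopy
images.

## Preprocessing

Grayscale is ITU-R 601 luma throughout.  Resizing is direct bilinear
resampling (nearest-neighbour for masks), no padding.

**Hair removal.**  Detection is the union of thresholded black-hat responses
over linear structuring elements of lengths {9, 15} px at orientations
{0°, 30°, …, 150°}.  The threshold default is 20 gray levels: hair strokes
(near-black on skin) respond at well over 100 gray levels, while realistic
correlated lesion texture (per-pixel std ≈ 6) produces responses up to
~15–20; 20 keeps stroke recall around 0.85–0.95 with under 1% false
positives on hair-free lesions.  Filling runs in fast-marching order (pixels
sorted by distance to the nearest known pixel) with inverse-distance-weighted
averaging over a radius-3 disc, preferring *originally known* pixels over
previously filled ones — without that preference the fill smears the
lesion/skin edge along any stroke that crosses it.  `remove_hair` iterates
detect-and-fill twice and returns the union mask: filled streaks can leave
faint residues at lesion-edge crossings that one refinement pass cleans up,
which is what makes a further application a near-no-op (<0.5% of pixels).

**Fallback segmentation** is Otsu thresholding on luma (lesion darker than
skin), largest connected component, hole filling.  It exists so the synthetic
pipeline runs end to end; real masks should come from a dedicated segmenter
and are accepted as input everywhere.

## Feature catalogue

All statistical texture families share one front-end: luma is linearly
rebinned to `Ng = 32` levels over the min–max of in-mask pixels (a common
radiomics default balancing histogram resolution against co-occurrence
sparsity at 224²; constant regions map to level 0).  Conventions:

- only in-mask pixels participate; a pair/run/zone counts only if every pixel
  involved is in-mask;
- directional families (GLCM, GLDS, GLRLM) use the four distance-1 offsets
  and are averaged, making them invariant under 90° rotations (tested at
  1e-9);
- entropies are base-2; gray levels are 1-based inside emphasis weights;
- zero-variance cases map to 0 (skewness, kurtosis, coefficient of variation,
  GLCM correlation), except NGTDM coarseness which is capped at 1e6 for a
  flat lesion;
- wavelet/spectral families (DWT, WP, HOS, FDTA, LBP, SFM) operate on the
  lesion bounding box with out-of-mask pixels filled by the in-mask mean, and
  raise an insufficient-support error when the box is smaller than the
  family's minimum (8 px sides for depth-3 wavelets).

Family contents, where a published count admits more than one reading:
GLCM emits the full 14-statistic Haralick set (the 11 commonly named plus
IMC1, IMC2 and the maximal correlation coefficient); GLDS the canonical five
difference statistics; GLRLM the 16-statistic set (11 classic Galloway-style
plus normalized non-uniformities, gray-level/run-length variances and run
entropy); GLSZM the 14 zone statistics; LBP energy+entropy of uniform-code
histograms at (R,P) ∈ {(1,8), (2,16), (3,24)}; HOS one normalized bispectral
phase entropy per Radon-projection angle (135°, 140°), with the bispectrum
accumulated directly as `X(f1)X(f2)X*(f1+f2)` over the principal region;
FDTA four Hurst-type exponents from intensity-difference scaling at four
dyadic resolutions; DWT 3-level `bior3.3` with mean/std of absolute
coefficients per subband (20 features); WP depth-3 `coif1` packets (64 nodes
× mean/std = 128).  DWT/WP counts are configuration-derived rather than
fixed catalogue constants.

**ABCD.**  Asymmetry is the mean symmetric-difference fraction of the mask
against its reflections across the two principal axes (through the centroid;
bilinear affine reflection keeps discretisation noise sub-pixel).  Note this
is small even for a half-disk (≈0.09): a shape reflected about an axis
through its own centroid largely overlaps itself; the measure responds to
asymmetry *about the centroid line*, which is the quantity the generator's
asymmetry knob controls.  Border is compactness `P²/(4πA)` with Crofton
perimeter.  Colour counts reference dermoscopy colours (white, red, light
brown, dark brown, blue-gray, black) occupying >1% of lesion pixels by
nearest-RGB assignment; the thresholds are this package's choice.  Diameter
is the maximum Feret diameter.

**Colour statistics.**  RGB and HSV are pooled over all in-mask channel
values (4 statistics each); CIE L\*a\*b\*, CIE L\*u\*v\* and YCrCb are
per-channel (12 each), total 44.

**Embeddings.**  The 2,048-dimensional embedding comes from the final global
average pooling layer of a 50-layer bottleneck residual network implemented
directly in numpy (im2col convolutions; He-normal weights drawn
deterministically from a seed; batch norm at its untrained identity state).
No training is performed and no weights are downloaded; the contract being
exercised is architectural (dimension, determinism, shape).  Pretrained
weights would require a deep-learning stack and can be substituted where one
exists.

## Ensemble feature selection

ReliefF with `k_neighbors = 10`, every instance an anchor, Manhattan
distances on features min-max scaled to [0,1]; a feature's weight rises with
its mean difference to nearest misses and falls with its mean difference to
nearest hits.  `M = 100` bootstrap subsets by default (the resampling is
stratified by class, preserving class counts — an imbalanced table can
otherwise produce near-single-class resamples).  Each base learner votes for
its `top_t = ⌈0.25·D⌉` features; features are ranked by votes, then mean
within-learner rank, then name (a total order, so results are reproducible).
`k_final` defaults to 35 for image-feature tables.  Selection is always fit
on training rows only; the selected names are then applied to test rows.

## Augmentation and fidelity

The sweep convention is `r = (n_min + n_syn)/n_maj ∈ (0,1]`, with
`n_syn = max(0, ⌈r·n_maj⌉ − n_min)`; the dataset-overview imbalance ratio
(majority/minority) is a separate, separately named quantity.  SMOTE uses
k = 5 Euclidean neighbours on z-scored features; synthetic rows are convex
combinations of real minority rows and therefore lie in the minority convex
hull.  CTGAN/TVAE are adapters over the `sdv` library (conditioning on the
label column by default, minority-only fitting by flag) and raise a
capability error when the library is absent — the SMOTE path never depends
on it.  Mode-specific normalization fits a Bayesian (variational) Gaussian
mixture of up to 10 components, prunes weights below 0.005, assigns each
value its highest-responsibility mode, and encodes (one-hot mode,
`(x − μ_k)/(4σ_k)`); the inverse reconstructs values exactly for the
assigned mode.

Fidelity: PMFs for continuous features use 20 equal-width bins over the
pooled min–max (the binning is this package's choice).  MAEP is the printed
sum (a `mean=True` flag divides by the bin count).  PCD uses the Frobenius
norm; constant columns contribute correlation 0.  RSVR counts exact
duplicates within the synthetic set only.

## Evaluation harness

Repeated stratified 80/20 train/test splits (5 repeats by default); ensemble
selection, augmentation, scaling and CV search all see training rows only;
test metrics are computed on untouched real rows.  Hyperparameters by
stratified 5-fold CV maximizing AUCROC: L1-logistic C over 10 log-spaced
points in [10^-1.5, 10^0.4]; KNN K in 1..11; RBF-SVM γ ∈ {1e-2..1e-5} and C
over 10 log-spaced points in [10^-0.9, 10^0.9]; tree depth 2..8 with minimum
split size scaled to the training set.  Ties go to the smaller-complexity
setting (more regularisation, smaller K, smaller depth), making the search
deterministic.  Class metrics use the 0.5 probability threshold with
melanoma (label 1) positive; reported std is over repeats, not folds.  All
per-repeat seeds derive from the master seed.

## Interpretability

The bootstrap test resamples within class (preserving class sizes), uses the
percentile interval (not BCa — the simplest method consistent with a plain
"95% confidence interval"), and applies no multiple-testing correction by
default (per-feature intervals are reported as-is; a Bonferroni flag
exists).  Its type-I error is calibration-tested at 0.05 ± 0.02 over 500
null simulations.  The exact Shapley oracle enumerates all `2^D` coalitions
(D ≤ 15) with background-mean imputation for absent features; it satisfies
efficiency, symmetry and dummy by construction and serves as the ground
truth for any library SHAP adapter.  UMAP projection is a seeded adapter
tagging points as real/synthetic × class.

## Problem sizes in the verification suite

The acceptance checks run at desk scale: one 224² lesion for catalogue
counts and the embedding; the 4×4 fixture for operator oracles; 1,000 random
PMFs for metric bounds; 500 null simulations (n = 200/class, M = 1000) for
calibration; 20 seeds of a 400×50 table for selection recovery; 10 seeds of
a 200×20 table with 3 repeats for the balance-ratio direction.  These sizes
give stable medians and binomial error bars comfortably inside the asserted
tolerances.

## Known limitations

- The hair detector's threshold trades recall against false positives on
  *texture*; on images with pigment-network-like fine structure it will flag
  (and smooth) some non-hair pixels.
- The asymmetry feature measures centroid-axis asymmetry only (see above).
- HOS phase entropy follows the bispectral-texture literature but an exact
  published formula for the two angle-indexed features does not exist; the
  implementation documents its own definition.
- The untrained backbone's embeddings are random projections with a residual
  topology: useful for contract and plumbing tests, not a substitute for
  pretrained representations in real studies.
- CTGAN/TVAE quality claims are not reproduced here; only the adapter
  contract and the always-available SMOTE path are exercised.
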