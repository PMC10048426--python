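# Methods

This note records the models, conventions and tunable parameters behind
`grainscan`, the choices made where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Synthetic scene model

The generator emulates a fixed top-down imaging rig: grains scattered on a
dark-blue tray (default RGB (20, 30, 90), chosen for strong grayscale
contrast against pale grains), captured at 2592×1944 with ~80 mostly
non-touching grains per scene and a small rate of salt-and-pepper pixels
from stray reflections.

A grain is a rotated filled ellipse whose normalized boundary radius is
modulated by a low-amplitude sinusoid (`jitter`, default 0.035 — enough to
break perfect symmetry without changing the fitted axes materially), shaded
darker toward the rim, overlaid with fine Gaussian surface noise (σ 2.5
intensity units), and optionally stamped with a bright chalky patch.
Setting `jitter=0` and a fixed angle yields the exact discrete ellipse,
which is what the geometry tests exploit. Lengths and widths are sampled
from per-variety normals clipped at ±3 σ, so rendered dimensions never
stray outside the declared profile range.

The eight default variety profiles are synthetic stand-ins, not measured
rice biometry: three long slender types (lengths 70–92 px, widths 13–15 px,
aspect ≈ 4.7–6.6), a short broken-basmati type, and four plump short-grain
types (lengths 36–52 px, widths 17–21.5 px), each with a small distinct
hull-color shift (creamy / yellowish / dull) and chalkiness probability
0.05–0.15. The classes are therefore separable through the same channels a
practitioner relies on for real rice — length, width, aspect ratio and hull
color — but with cleaner margins than field samples would show.

Placement is rejection sampling: a sprite is accepted when its mask dilated
by `min_gap` (Chebyshev pixels, default 4) misses every earlier grain, so a
positive gap guarantees no 8-connected adjacency. Failure after a bounded
number of attempts raises an error reporting how many grains were placed.
Salt-and-pepper noise is applied last and never alters the label raster.
A single `numpy` generator seeded from the scene spec drives every
stochastic step, making scenes byte-reproducible.

What the generator does *not* model: perspective and lens distortion,
uneven illumination and shadows, specular highlights, broken or overlapping
grain clusters, dust, and the intra-variety covariance structure of real
rice. Passing the end-to-end tests therefore demonstrates that the pipeline
machinery is correct and well-calibrated on its stated image model — not
that the reported accuracies transfer to field photographs.

## Segmentation

The chain is median filter → grayscale → Otsu → binarize → erode → label →
watershed → extract.

- **Median filter**: 5×5 per RGB channel. Border policy is symmetric
  (edge-replicating) reflection — the convention of
  `scipy.ndimage.median_filter(mode="reflect")` — and the test oracle pads
  the same way.
- **Grayscale**: luma weights 0.299/0.587/0.114, rounded to uint8.
- **Otsu**: implemented from the histogram up, evaluating all 256 candidate
  thresholds with the lower class {k < t} and upper class {k ≥ t}. The full
  per-threshold trace (class probabilities, class means, between-class
  variance) is kept on the result object. Ties break to the smallest
  maximizing threshold (a strict `>` update while scanning upward keeps the
  first maximizer). A histogram with fewer than two occupied levels is
  rejected: no threshold separates one class.
- **Binarization**: foreground = gray ≥ threshold, because grains are
  brighter than the dark tray. The comparison direction is a convention;
  the reference-implementation cross-check in the tests confirms the same
  partition as `skimage.filters.threshold_otsu` on bimodal images.
- **Erosion**: one pass of a full 3×3 structuring element, border treated
  as background (`iterations` exposed for heavier marker separation).
- **Markers**: 8-connected components, numbered in raster-scan order of
  first pixel.
- **Watershed**: `skimage.segmentation.watershed` on inverted grayscale
  (bright grain interiors become basins), restricted to the Otsu
  foreground, with watershed lines kept; ridge pixels inside the foreground
  are recoded −1 so {background} ∪ {ridge} ∪ {labels} partitions the
  raster and every marker keeps its label.
- **Merged-grain rejection**: touching grains whose markers fuse produce
  one oversized region that cannot be split, so regions with area > 1.8 ×
  the scene's median region area are rejected and reported (never silently
  dropped); a symmetric undersized filter (< 0.2 × median) removes noise
  specks. Both factors are configurable. The area-vs-median rule assumes
  scenes are size-homogeneous — true for single-variety scenes, the layout
  of the emulated dataset (one variety per image; only the validation
  mixtures blend two). In a scene mixing the largest and smallest default
  profiles the longest grains can exceed 1.8 × median and would be falsely
  rejected; raise `merge_factor` for deliberately heterogeneous scenes.

## Features

The default registry is 18 geometry + 288 color + 48-bin × 6 channels +
24 texture = 330 named features, serialized as a JSON manifest next to
every feature table. (Published feature sets in this area are sometimes
tallied inconsistently; the explicit registry makes this package's
accounting unambiguous.)

- **Contour**: Moore-neighbor tracing with Jacob's stopping criterion;
  unique boundary pixels in clockwise order; filling the contour
  reconstructs the (hole-free) mask.
- **Ellipse fit**: second-order image moments via `regionprops` —
  deterministic and mask-based; major/minor axis lengths serve as grain
  length L and width l.
- **Perimeter**: Crofton four-direction estimate, whose bias on smooth
  convex shapes is far smaller than the chain-code estimate; with it the
  roundness of a discrete disk of radius 20 is 0.97 and dimensionless
  shape features are scale-stable to ≈3% above ~100 px grain length.
  Discretization tolerance for shape identities is ±0.05.
- **HSV**: standard sector formula (V = max, S = (max−min)/max, hue by
  sector), hue wrapped to [0, 360) then rescaled to 0–255 and saturation
  to 0–255 so one uniform binning (floor(v·48/256)) applies to all six
  channels.
- **Color histograms** are computed over masked grain pixels by default to
  avoid background contamination; a bounding-box mode
  (`masked_histograms=False`) is available for fidelity with rigs that
  histogram the whole box.
- **GLCM**: 256 gray levels at unit offsets (0,1), (−1,1), (−1,0), (−1,−1)
  for 0°/45°/90°/135°; pairs counted only when both pixels are inside the
  grain mask; not symmetrized, not averaged over angles (per-angle
  statistics are the features). The texture quantization (256) is
  independent of the histogram quantization (48).
- **Haralick statistics**: contrast, dissimilarity, homogeneity
  Σp/(1+|i−j|) (linear inverse difference — note `skimage.graycoprops`
  uses the squared form), ASM, energy = √ASM, and correlation in the
  standard form Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) with moments from the marginals of
  the normalized matrix; correlation of a zero-variance distribution is
  defined as 1 (constant-image limit).

## Classification

Estimators come from scikit-learn; the evaluation protocol is computed in
the package from the confusion matrix so its invariants hold by
construction and are cross-checked against scikit-learn in tests.

- Scale-sensitive models (LR, MLP, every SVM kernel) run inside a
  standardization pipeline; trees consume raw features. SVMs fit Platt
  probabilities so every model exposes per-class scores for ROC analysis.
- Stratified k-fold (default k = 10, shuffled, seeded) with per-class
  minimum-count validation; folds are deterministic given the seed.
- Headline metrics are macro (unweighted) averages — appropriate when the
  minority class (the adulterant) matters as much as the majority —
  with support-weighted F1 also reported.
- Feature selection: impurity importances from a fitted tree model,
  normalized to sum 1; default keeps the top 59, threshold mode available.
- Grid search is an exhaustive Cartesian product scored by CV mean macro
  F1, ties to the first combination in deterministic grid order. The
  default RF grid covers n_trees ∈ {100, 200, 400}, max_depth ∈
  {8, 16, ∞}, min_samples_split ∈ {2, 5, 10}, min_samples_leaf ∈ {1, 2, 4}.
- ROC: one-vs-rest threshold sweep over the sorted unique scores plus
  sentinels, AUC by trapezoid (equal to the Mann–Whitney statistic, which
  the tests verify); a class absent from the test set yields a flagged
  undefined curve rather than an exception.
- Prediction ties (equal scores) resolve to the lowest class index in
  label order, scikit-learn's convention.

## Pricing

Grain weight is unobserved, so variety i contributes the volume proxy
Lᵢ·lᵢ² (length × width²) weighted by its price pᵢ. All three factors —
actual (true counts), predicted (classifier counts) and unadulterated
(pure majority-variety sample) — are computed **per grain** (weighted sum
divided by grain count); this puts them on one scale so their comparison
is meaningful, which the summed forms would not be when the pure-sample
factor carries an extra count term. A `total=True` flag restores the
summed convention. The majority variety is taken from the truth when
available, else from predictions; count ties break to the higher-priced
variety. The adulteration flag fires when predicted and unadulterated
factors differ by more than a relative margin, default 5% — no published
cutoff exists for "significant", and 5% sits well above the pure-sample
noise floor while catching a 10%-by-count substitution of a cheaper
variety. L and l default to per-variety means estimated from a labeled
feature table; an explicit price table (CSV) overrides. The bundled
`EXAMPLE_PRICES` are synthetic stand-ins ordered like real market premiums
(basmati > masuri > kolam).

## Problem sizes and numerical conventions

The test and reproduction workloads use: 800×600–1200×900 canvases for
multi-scene work with the full 2592×1944 canvas for the protocol-scene
recovery run; 40 grains per variety (320 training grains) for the
cross-validation study; and a 50:30 two-variety mixture for the pricing
protocol. These sizes give stable statistics (CV folds of 32 samples;
binomial bounds on noise checks) while keeping a full run in minutes on
one CPU. Coordinates are (row, col), bounding boxes 0-based half-open,
connectivity 8-wise throughout. Feature CSVs are written with `%.17g`
floats and round-trip bit-exactly under pandas' round-trip parser.

## Known limitations

- The synthetic benchmark's class margins are cleaner than real rice;
  accuracies reported on it are upper bounds of machinery correctness, not
  field performance.
- Touching grains are rejected, not split; heavily clustered scenes lose
  throughput.
- The merged-grain filter's scene-median calibration assumes
  size-homogeneous scenes (see above).
- No illumination correction: the luma/Otsu path assumes the dark-uniform
  background of the emulated rig.
- Price factors are proxies (currency × px³ per grain), not currency
  amounts; only ratios and relative errors are meaningful.
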