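# Methods

## Problem and model

`mcica` detects clusters of microcalcifications — tiny, bright, high-attenuation
calcium deposits whose grouping (≥3 within roughly 1 cm²) is an early mammographic
sign of breast cancer — in optical-density (OD) images. The pipeline is:

1. **Calibration.** Raw grey levels are mapped to OD by an affine calibration,
   either linear in grey (`od = a·g + b`) or linear in `log10(grey)`, clamped to
   a physical range (default 0–4 OD). Both families cover the scanner classes
   found on digitized film; exact coefficients are supplied per image in a JSON
   sidecar rather than hard-coded. Downstream stages consume raw OD directly,
   with no per-image renormalization: the calibrated OD scale is already
   common across images, and the ICA column-centering step absorbs the global
   offset.
2. **ICA features.** Square windows (odd side `w`, 3–81 px) centred on labelled
   prototype pixels form a patch matrix `X` (rows = vectorized windows). Each
   column (pixel position) is mean-centred; the centred data are prewhitened by
   projection onto the top `n` principal directions with unit output variance
   (matrix `K`, ddof=1 convention so the empirical covariance of `X_c K` is
   exactly the identity); FastICA (log-cosh contrast, symmetric decorrelation,
   tol 1e-4, max 200 iterations) estimates the orthonormal rotation `W` with
   `S = X_c K W` the recovered sources. A pixel's feature vector is
   `F = ((R − column_means) K) W` for its window `R`; per-patch DC removal is
   deliberately *not* applied — only the training-set column means are
   subtracted. Patient age can be appended as one extra feature, scaled
   linearly from [27, 91] years onto [−1, +1] and clamped outside that range.
3. **Classification.** A single-hidden-layer MLP (logistic sigmoid on hidden
   and output layers; one output per prototype class: clustered-malignant,
   isolated, normal) is trained full-batch on a sum-of-squares error with
   iRPROP− (η+ = 1.2, η− = 0.5, Δ0 = 0.1, Δmax = 50, Δmin = 1e-6 — the standard
   published constants; on a gradient sign flip the step shrinks and that
   update is skipped). Weights initialize uniformly on [−0.3, 0.3]. The epoch
   snapshot with the best validation success rate is kept, stopping after 50
   improvement-free epochs (max 1000). A sweep over hidden sizes (50–200) with
   several random restarts keeps the single best network; ties break toward
   fewer hidden units, then the lower restart index. The success rate is the
   overall fraction of analyzer-correct validation patterns under a plain
   winner-takes-all rule, with UNCLASSIFIED counted as an error.
4. **Analyzers.** Output decisions use SNNS-style rules: `402040` accepts a
   class iff its activation ≥ h = 0.55 while all others stay ≤ l = 0.45; `WTA`
   accepts the unique argmax iff it exceeds h (presets WTA0–WTA3 with
   h = 0, 0.5, 0.55, 0.6). Ties in WTA are UNCLASSIFIED (conservative and
   deterministic). A pixel is a detection when its decision falls in the
   positive class set (default: both microcalcification classes).
5. **ROI building.** Detection maps are cleaned of 8-connected components
   below 2 px (isolated pixels) or above 100 px (artifact guard; both
   configurable), surviving components become objects with sizes and
   centroids, and a density map counts object centroids inside the square
   neighbourhood of physical side 1 cm (area exactly 1 cm²; a disc of equal
   area is available) centred at each pixel. The window side in pixels is
   `round(10000/pixel_size_um)` forced odd; centroids are binned to their
   nearest pixel before counting, and the square count uses an exact
   integral-image box sum with zero padding (windows clip at borders).
   Support pixels with counts ≥ 3 are grouped 8-connected into disjoint ROIs;
   the ≥3 reading of the density rule is implemented (a strict >3 is one
   `threshold=4` away).
6. **Scoring.** Per image, an ROI overlapping any malignant truth region by at
   least one pixel (minimum overlap fraction configurable, default 0) is a TP,
   otherwise an FP; unmatched malignant regions are FNs (one each); a healthy
   image with no ROIs is one TN. Sensitivity is TP/(TP+FN) — the
   true-positive proportion — and FPi is FP divided by the number of evaluated
   images. FROC operating points trace (FPi, sensitivity) across analyzers;
   activation maps are computed once per image and reused across analyzer
   thresholds. A single ROI overlapping two truth regions counts as one TP
   while both regions count as matched.

## Synthetic phantoms

Real screening-mammography archives cannot ship with the package, so every
test runs on phantoms: ~1.4 cm tiles (320×320 px at 43.5 μm/pixel, 12-bit-style
OD scale) containing one malignant cluster of 5–8 deposits spread over a
0.25 cm radius, two isolated deposits, two vessel-mimic line segments, one
large-blob artifact, and a background of mean OD 1.5 plus a smooth correlated
field (σ = 8 px, amplitude 0.15 OD) plus white noise (σ = 0.03 OD).
Microcalcifications are anti-aliased discs with Gaussian-tapered edges
(3–6 px diameter clustered, 5–9 px isolated, 0.4–0.8 OD contrast). Isolated
deposits are drawn larger than clustered ones so the two prototype classes are
visually distinct; only two isolated deposits are placed per tile because
three within ~1 cm² would itself constitute a cluster. Cluster ground-truth
polygons are the convex hull of member centroids dilated by two object radii,
mimicking loose free-form annotations. All randomness derives from a single
seed; generation is bit-deterministic.

Phantoms deliberately omit anatomic breast texture, the skin line and
pectoral muscle, benign-vs-malignant morphology differences, and scanner
noise spectra. Passing the phantom suite therefore demonstrates that the
pipeline's mechanics — feature extraction, training, thresholding, density
grouping, scoring — are correct and deterministic; it does not certify
clinical-grade performance on real mammograms, where contrast is far subtler
and backgrounds far richer.

## Numerical and design choices

- **Whitening/rotation split.** `K` is computed by SVD in-package so the
  prewhitening and unmixing factors are separately inspectable; the rotation
  comes from scikit-learn's FastICA run on the pre-whitened data. Orientation
  of the factors is pinned by the consistency requirement that features at a
  training location reproduce the corresponding source row to 1e-8.
- **Non-convergence** of the fixed-point iteration raises an error carrying
  the iteration count; orchestration code may downgrade it to a warning
  (patch data at small sample sizes can stop just short of tol without
  harming the downstream classifier).
- **Border policy.** Pixels whose window would leave the image are excluded
  from both patch sampling and diagnosis; the detection map keeps a false
  margin of half the window width.
- **Polygon rasterization** is an exact inclusive pixel-centre test
  (`covers`), not a scanline approximation, so region areas match a
  brute-force point-in-polygon scan identically.
- **Density semantics.** Density counts *objects* (post-labelling), not raw
  pixels, and centroid binning to the nearest pixel makes the integral-image
  path agree exactly with the brute-force Chebyshev-distance oracle.
- **Degenerate inputs.** Empty detection maps yield empty object lists and
  zero density; a neighbourhood window wider than the image is a geometry
  error; sensitivity is undefined (an error, not NaN) when no positives exist.

## Default problem sizes

End-to-end experiments default to 20 phantoms split 10/5/5 by image
(learning/validation/test), a 9-px window, 20 ICA components, hidden sizes
{50, 100} with 2 restarts, and the WTA1 analyzer — small enough to run in
seconds on one CPU, large enough that every stage operates at realistic
settings. The reproduction script (`scripts/acceptance.py`) uses these
defaults, a 6-phantom perfect-detector oracle, mixtures of 2–8 sources at
10⁴ samples for ICA validation, and a reduced 8-phantom configuration for the
bit-determinism check.

## Known limitations

- The phantom's structured background is stationary Gaussian texture; ICA
  bases learned from it are poorer than bases learned from natural mammogram
  statistics, and analyzer thresholds that are comfortable here may need
  retuning on real data.
- The 1 cm² density window assumes pixel sizes fine enough that the window
  spans ≥1 px and no larger than the image; whole-breast images at coarse
  resampling may need the disc variant or explicit tiling.
- Case-level (two-view) scoring, ROC on pixel probabilities and statistical
  comparison between FROC curves are out of scope.
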