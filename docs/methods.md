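# Methods

## The analysis

`periquant` quantifies how far lineage-labeled cells have invaded a tissue
and how they distribute relative to the vasculature, from multi-channel
fluorescence images. The motivating system is the embryonic mouse heart:
epicardial-derived cells (EPDCs) carry a membrane-GFP lineage reporter,
the coronary vascular plexus is stained for CD109, and DAPI marks nuclei.
The pipeline is deliberately simple and fully deterministic:

1. **ROI restriction.** Analysis is confined to a region of interest
   (typically the compact myocardium, supplied as a polygon or mask).
   Pixels outside the ROI are zeroed and excluded from all histograms and
   objects.
2. **Otsu segmentation.** Each channel is thresholded per image with Otsu's
   method over ROI pixels (256 bins spanning the ROI min–max intensity
   range). Foreground is *strictly above* the returned cut; the lowest
   maximizing cut wins ties. Foreground is decomposed into connected
   components (8-connectivity by default) and components below
   `min_area_px` (default 5) are discarded as speckle.
3. **Nearest-neighbor proximity.** For every GFP object, the Euclidean
   pixel distance to the nearest CD109 object — centroid-to-centroid by
   default; an optional `boundary` mode measures to the nearest CD109
   pixel, with containment counting as zero. Distances are computed by an
   explicit all-pairs scan; ties go to the lowest CD109 object id.
4. **Threshold and classification.** The classification cut is the
   arithmetic mean of pooled control-genotype distances (`derive_threshold`;
   per-image and per-specimen averaging are selectable alternatives). The
   control-derived value reported for the original embryonic heart dataset,
   22 px, ships as the fixed-mode default. An object is *perivascular* when
   its distance is strictly below the cut and *interstitial* at or above it
   (so d = 21.9 → perivascular and d = 22.0 → interstitial at T = 22).
5. **Area quantification.** Per-field "fluorescence area" is the total
   Otsu-foreground pixel count after size filtering — one consistent rule
   across GFP/CD109/DAPI. GFP area is normalized to DAPI area (field-size
   control), then to the control group so the control mean is exactly 1.0.
6. **Statistics.** Fisher's exact test (two-sided, point-probability rule)
   for per-specimen binary outcomes; uncorrected chi-square tests of
   independence for class-count and cluster-frequency tables (the 2×2
   statistic therefore equals `n(ad−bc)²` over the product of margins);
   pooled-variance Student t-tests (Welch by flag) for group means at both
   the image and specimen level; OLS regression with R² strength tiers
   (≥ 0.75 substantial, ≥ 0.50 moderate, ≥ 0.25 weak); 95% data ellipses
   (sample mean/covariance scaled by the chi-square(2 df) 0.95 quantile).
7. **Scratch closure.** In explant scratch assays the acellular wound is
   the union of connected sub-Otsu background components intersecting the
   scratch ROI; closure is `1 − area_t/area_0`. An intensity-constant frame
   (fully closed field) is read as zero acellular area; a zero wound at
   t = 0 is an error; area increases over time are warned about, not fatal.

## Synthetic scenes and what they do (and do not) emulate

Because the pipeline's real inputs are microscopy that cannot be shipped,
a generator produces scenes with exact ground truth:

- **Vessels** are disks placed uniformly (radius 6 px by default, 20 per
  512×512 field).
- **GFP cells** (radius 3 px, 200 per field) are a two-component mixture:
  with probability `perivascular_fraction` (default 0.5) a cell is coupled
  to a uniformly chosen vessel at offset `|Normal(0, coupling_scale_px)|`
  (default 5 px) in a uniform direction; otherwise it is uniform over the
  field. The half-normal coupling is a modeling choice — the real offset
  distribution is unknown — and is parameterized, not asserted.
- **Genotype effect** is selective interstitial depletion: each
  interstitial cell is retained with probability `interstitial_retention`
  (1.0 = control), perivascular cells always. Expected cell count is
  `n_gfp · (p_f + (1−p_f)·retention)`.
- **Nuclei** are uniform disks; **noise** is optional Poisson resampling of
  photon-scaled intensities followed by additive Gaussian noise, both off
  by default so oracle tests are exact.
- **Determinism**: one seed per scene; cohort seeds are derived
  counter-style from `(master seed, genotype, specimen, image)`, so any
  sub-cohort regenerates identically. Default cohort geometry is
  4 specimens × 6 images per genotype.
- `min_separation` optionally enforces a `2·radius+1` centroid separation
  per channel so that rendered disks never merge and segmentation is
  exactly lossless; it is used by recovery tests.

Not emulated: tissue texture and autofluorescence, vessel elongation and
branching, point-spread blur, cell-shape variation, overlapping
nuclei/cell structures beyond disk overlap, 3-D sectioning effects.
Passing recovery tests therefore shows the *algorithmic* chain is correct
and calibrated under the stated spatial model — not that segmentation is
robust to real histology.

## Calibration studies (simulation experiments)

- **Threshold calibration.** With `perivascular_fraction = 1` the mean
  nearest-vessel distance has the closed form `σ√(2/π)`. The study uses
  sparse vasculature (5 vessels, kept away from the frame border) so the
  closed form's assumptions hold — the coupled vessel is nearest, and no
  boundary redraws truncate the offsets — and compares the derived
  threshold against it using a clustered (per-image) standard error, since
  cells within an image share one vessel configuration. Mixture conditions
  have no closed form (uniform-point-to-nearest-disk distances), which is
  why calibration uses the pure-coupling condition.
- **Classification recovery.** Distance-threshold classification has an
  irreducible Bayes error: a uniformly placed "interstitial" cell may land
  beside a vessel and is then indistinguishable from a coupled cell. With
  the default 20-vessel density roughly 10–20% of interstitial cells fall
  below a pooled-mean threshold, so generative labels cannot be recovered
  to binomial accuracy under those conditions — by construction, not by
  implementation error. Recovery is therefore verified in a well-separated
  regime (4 vessels per field, 5-px coupling, light per-vessel load with
  `min_separation`, fixed 22-px cut) where the misclassification rate is
  well below the 3-s.e. binomial band.
- **Redistribution power.** Under the study-condition defaults with mutant
  `interstitial_retention = 0.5`, 50 full-pipeline replicates of the
  4×6-image two-genotype cohort measure how often the class-count
  chi-square is significant at α = 0.05 and how often the mutant mean NN
  distance falls below control (the depletion-consistent direction).
- **Thinning recovery.** The mutant group mean of `normalized_gfp` should
  equal `p_f + (1−p_f)·retention` (0.58 at p_f = 0.3, retention = 0.4).
  Overlapping rendered disks make fluorescence area sub-additive in cell
  count (a union-area effect of a few percent under the default coupling),
  so this study enables `min_separation`, under which area is proportional
  to count and the analytic expectation applies. Six cohort replicates give
  the across-replicate standard error.
- **Invasion regression.** The default generator fixes cell and vessel
  counts per field, so GFP and CD109 areas are uncorrelated across fields.
  The regression study instead draws a per-field latent intensity that
  drives the vessel count and, mixed half-and-half with independent noise,
  the cell count — an analytic field-count correlation of
  `0.5/√(0.5² + 0.5²) ≈ 0.71`, i.e. a moderate-strength setting — and fits
  measured areas from the full pipeline over 3 specimens × 18 fields.

## Numerical choices

- **Otsu exactness.** The between-class-variance argmax is computed in
  exact arithmetic: affinely spaced bins (every image histogram) reduce to
  Python-integer arithmetic over bin indices (the argmax is invariant under
  affine maps of bin values), and arbitrary histograms use
  `fractions.Fraction`. Floating-point near-ties therefore cannot move the
  cut; exact ties resolve to the lowest cut.
- **Histogram binning**: 256 uniform bins over the ROI min–max range, right
  edge closed in the last bin; the returned threshold is the center of the
  highest background bin.
- **NN distances** use numpy broadcasting of the textbook formula (square,
  sum, square root), never an approximate spatial index, so results match a
  brute-force scan bit-for-bit.
- **Degenerate inputs**: constant channels raise (or, in the batch driver,
  are reported as "no objects"); fields with zero DAPI area are flagged
  invalid and excluded from group means; images with zero CD109 objects are
  excluded from distance statistics but retained for area statistics, with
  an audit trail; zero-variance t-tests return p = 1 (equal means) or p = 0
  with a warning (unequal); collinear point sets raise a degenerate-ellipse
  error.
- **Coordinates** are 0-based `(row, col)`; centroids are unweighted pixel
  means. Classification stays in pixel units (uniform magnification is
  assumed); a `pixel_size_um` field supports µm conversion in reports only.
- The cluster-frequency significance preset α = 0.0025 is applied as a
  given constant; no additional multiple-testing layer is added. Per-row
  flags in K×2 tables come from uncorrected row-vs-rest 2×2 chi-squares.

## Problem sizes

Default simulation studies use 512×512 fields, cohorts of 4 specimens × 6
images per genotype, 50 replicates for the power study, 6 for thinning
recovery, 24 images for threshold calibration, 1000 null tables for the
type-I check, and 10⁵ draws for ellipse coverage. These sizes give
standard errors comfortably inside every acceptance band while keeping a
full run to a few minutes on one CPU.

## Known limitations

- No watershed splitting: touching same-channel objects merge into one
  component (mitigated in tests via `min_separation`; real tissue will
  undercount clustered cells and shift centroids).
- Per-image Otsu assumes a bimodal-enough intensity histogram; very sparse
  or empty channels threshold on noise (the `min_area_px` filter is the
  only guard).
- The unit-of-analysis ambiguity for group tests (image vs specimen) is
  resolved by computing both; specimen-level is the recommended inferential
  unit since images within a specimen are not independent.
- Whether DAPI normalization should use area or nucleus count is an open
  modeling question; area is the default, count is available via the
  segmentation tables.
- Scratch detection assumes a GFP-confluent field; phase-contrast imagery
  is out of scope.
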