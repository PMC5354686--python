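# Methods

This note records the models behind `bpeq`, the tunable parameters and
their defaults, the design choices made where the method left them open,
and what the synthetic data can and cannot show.

## The quantity

BPER (background parenchymal enhancement rate) is the volume ratio of
enhanced fibroglandular tissue (Ve) to total fibroglandular tissue (Vt) of
one breast, expressed in percent, at a fixed post-contrast phase (early =
2 min, mid = 4 min, late = 6 min after injection). Both volumes are voxel
counts on the same grid, so the ratio is spacing-free; voxel spacing only
converts counts to mm³ for reporting. At the subject level the measurement
target is the mean of the two breasts for controls and the contralateral
(lesion-free) breast for cancer and benign subjects, which keeps the lesion
itself out of the measurement.

## Whole-breast segmentation

Each axial slice is processed in 2D. Both boundaries of the breast are
single-valued curves in the prone orientation — one row (anterior–posterior
coordinate) per column — so they can be found by dynamic programming over a
cost grid:

* cost = 1 − (oriented, Gaussian-smoothed intensity gradient along rows,
  rescaled to [0, 1]). The skin line is a dark→bright (air→tissue) edge,
  the chest wall bright→dark (fat→thorax); using the signed gradient keeps
  each search from locking onto edges of the wrong polarity.
* The DP returns the globally cheapest path with per-step row change
  ≤ `smoothness` (default 2). Ties are resolved toward the anterior row for
  the skin and the posterior row for the chest wall, column by column from
  the left, making the output deterministic.
* Cross-slice continuity: the central slice is delineated inside a ±4-voxel
  band around threshold-derived initial curves (first tissue row per column
  for the skin; last bright-tissue row for the chest wall, with thresholds
  self-calibrated from anterior/posterior reference strips). Every further
  slice is constrained to ±`band_width` (default 3) around its already
  segmented neighbour. This makes the anatomical continuity of both
  surfaces an explicit constraint rather than a hope.

The breast region on a slice is the set of voxels strictly between the two
curves, split left/right at the midline column. An optional fixed-fraction
in-plane crop around the body's intensity centroid restricts processing to
a volume of interest; default is no crop (the phantom's field of view is
already tight).

Degenerate inputs: a constant central slice (no anterior edge) raises an
error naming the slice; a band that is empty or disconnected under the
smoothness bound raises explicitly.

## FGT segmentation

Fuzzy c-means on the 1D intensity sample of all voxels of one breast (3D,
not per slice — pooling slices stabilises the cluster estimates). Updates
are the standard alternating memberships/centroids with fuzziness exponent
m = 2, tolerance 1e-5 on the objective decrement, ≤ 300 iterations, and
deterministic quantile-spaced initial centroids (seeded random restarts are
available but not needed for 1D intensity data). The number of clusters is
chosen in k = 2..5 by minimising the Xie–Beni index (compactness over
separation); the Bezdek partition coefficient is available as an
alternative. Ties prefer the smaller k. Candidate k values exceeding the
number of distinct intensities are skipped — on a noise-free image the
sample may contain exactly two values, where only k = 2 is fittable.

On fat-suppressed pre-contrast images FGT is the highest-intensity cluster
(configurable to the top two for k > 2). A guard refuses the all-fat
breast: if the total centroid spread is below 4 robust noise units
(1.4826 × MAD of the sample), no cluster is separable as tissue and the
call fails loudly rather than returning fat as FGT.

## Enhanced-FGT segmentation

Enhancement is measured on the voxel-wise subtraction (post − pre, no
clipping, no motion registration — a documented limitation). The noise
level σ̂ of the subtraction is estimated as 1.4826 × median absolute
deviation over a non-enhancing reference region — by default air anterior
of the skin line with a 3-voxel standoff; the MAD keeps a few enhancing
outliers from inflating the estimate. A voxel of FGT counts as enhanced if
its subtraction value exceeds z·σ̂ with z = 3, i.e. a one-sided
false-positive rate of Φ(−3) ≈ 0.00135 per FGT voxel under the pure-noise
null — a calibration the tests verify by Monte Carlo. The threshold is
global per volume; raising z can only shrink the enhanced mask.

## Risk statistics

* Mann–Whitney U with midrank ties; two-sided p by exact enumeration over
  assignments of the pooled midranks when both samples have ≤ 20
  observations, otherwise a tie-corrected normal approximation without
  continuity correction. The U convention counts pairs with x > y (ties
  half).
* ROC: empirical, "score ≥ threshold" is test-positive. AUC is the
  trapezoid area and equals U/(n₁n₂) exactly, ties included — an identity
  the tests assert to 1e-12. The AUC confidence interval uses DeLong's
  variance of placements (Hanley–McNeil available).
* Phase selection: the phase with maximal AUC, earlier phase on ties.
* Operating point: Youden's J = sensitivity + specificity − 1, lower
  threshold on ties; J = 0 (no cutoff beats chance) is flagged.
* Odds ratio: OR = ad/bc on the 2×2 table of high/low BPER (≥ cutoff is the
  exposure) by case/comparison group, with the Woolf logit 95% CI,
  exp(ln OR ± 1.96·√(1/a + 1/b + 1/c + 1/d)), and Pearson's chi-square
  without continuity correction. A zero cell triggers a flagged
  Haldane–Anscombe +0.5 fallback, never a silent one.

On the published 2×2 counts the Woolf interval reproduces the printed
bounds at their 1-decimal precision, with one caveat worth recording: the
two published tables evidently use different decimal conventions (one is
consistent with round-half, the other with truncation toward zero), and the
package's checks accept a bound when either convention maps the computed
value to the printed one. All four odds ratios round exactly to the printed
values. No multiple-testing correction is applied anywhere, matching the
analysis design.

## The phantom

The generator emulates a prone, axial, fat-suppressed T1 acquisition on a
rows × cols × slices grid (default 128 × 128 × 48 at 1.5 mm — a desk-scale
analogue of a 360 × 360, 1.5 mm-slice protocol):

* chest wall: an anteriorly convex low-order polynomial per slice, with a
  smooth bounded wobble across slices (|step| ≲ 1 voxel), so the
  continuity assumption is satisfied but not trivial;
* two breast lobes anterior of it, tapering across slices, plus a thin
  subcutaneous layer spanning the full width; lobe height/width are chosen
  so the skin slope stays within the delineator's default smoothness bound;
* FGT as blobby top-ranked regions of a Gaussian-correlated random field in
  each lobe core at a prescribed volume fraction (default 0.30), kept clear
  of skin and chest wall so the strong FGT–fat edges stay outside the
  boundary search bands — mirroring the subcutaneous and retromammary fat
  layers of real anatomy;
* enhancement: a prescribed, non-decreasing fraction of FGT voxels per
  phase (default 0.25/0.40/0.50) recruited along a fixed smooth-field
  ranking, so phase masks are nested and the true BPER is exact by
  construction;
* intensities air 5 / thorax 40 / fat 100 / FGT 180, phase uplifts
  80/110/140, i.i.d. additive Gaussian noise (default σ = 5, i.e. 5% of
  fat). Gaussian rather than Rician noise is deliberate: it keeps the
  z·σ̂ threshold's null calibration exactly the normal tail. Real magnitude
  images are Rician; at the SNRs of breast tissue the difference is small,
  but air-region statistics differ, which is why the noise estimate uses
  the subtraction image (approximately Gaussian by symmetry) rather than
  the magnitude image.

What passing the phantom tests shows: the pipeline's logic, calibration and
numerical behaviour are correct under known geometry, ideal fat
suppression, no motion, no bias field, no partial volume. What it does not
show: robustness to coil inhomogeneity, motion between phases, imperfect
fat suppression, or anatomy outside the two-lobe model. Those belong to
clinical validation, not to this package's synthetic scope.

## The cohort simulator

Subject-level BPER per phase is drawn from truncated normals on [0, 100]
with per-(menopausal status, group, phase) location/scale, defaults chosen
so medians satisfy cancer > benign > control, premenopausal >
postmenopausal, and increase with phase. The location shift between cancer
and control at each stratum's discriminative phase was set so the exact
model AUC (computed by quadrature of P(X_cancer > X_control) under the
truncated model) lies in the 0.65–0.70 band: 0.678 premenopausal/mid,
0.664 postmenopausal/early. Groups are sized equally with a fixed
premenopausal fraction of 47/101, matching the matched three-group design
of 101 subjects per group. The simulator reproduces the qualitative
orderings and effect sizes of the study population, not its exact
distributions, which were never published per subject.

## Problem sizes and determinism

Tests and the acceptance script run phantoms at 96–128 voxels per in-plane
axis and 32–48 slices, cohorts of 101–3000 subjects per group, 100-grid
dynamic-programming enumerations (grids ≤ 8×8, dyadic costs so float
comparisons are exact), and 10⁵-voxel noise-null calibrations — sizes at
which every Monte-Carlo tolerance quoted above has comfortable margin.
All randomness flows through explicit integer seeds; equal seeds give
byte-identical volumes, tables and CSV outputs.

## Known limitations

* No motion registration before subtraction; no bias-field correction.
* The boundary delineator assumes the prone-axial orientation convention
  and single-valued boundaries per column; inputs must be reoriented by the
  caller.
* The VOI extractor is a fixed-fraction centroid crop, not a detector.
* Exact Mann–Whitney enumeration is conditional on the observed tie
  pattern; for heavy ties at small n this is the standard conditional test,
  not an unconditional one.
* DeLong CIs assume independent subjects; clustered designs (both breasts
  of one subject as separate observations) are out of scope — the
  subject-level measurement rule exists precisely to avoid that.
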