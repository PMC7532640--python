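# Methods

## The region of interest

Every feature consumes a `LesionROI`: an 8-bit grey image, a single-component
binary mask, the ordered boundary traced from that mask, and the mask
centroid. Coordinates are 0-based `(row, col)`, origin top-left; the row axis
is depth (beam direction) and the column axis is lateral. The skin is assumed
parallel to the top image edge — standard linear-probe geometry — so
"horizontal" always means the column axis. Angles are measured from +col
toward +row, i.e. clockwise as displayed.

Contours arrive either as JSON vertex polygons or as 0/255 mask images.
Polygons are filled with scikit-image's boundary-inclusive scanline fill
(an integer-cornered 31×31 square rasterizes to exactly 961 pixels; a
360-vertex circle of radius 30 lands within 0.5% of πr²), holes are filled,
and a single connected component is required. RGB input collapses by ITU-R
601 luminance, since clinical exports are often 3-channel grey.

### Boundary tracing and the two boundary measures

The boundary is traced with Moore neighbour tracing, clockwise, stopping
when the initial transition repeats (a plain position test loops forever on
one-pixel-wide spurs, which revisit pixels). The traced set equals exactly
the foreground pixels with a 4-adjacent background neighbour — the
8-connected inner contour; every such pixel is also 8-adjacent to
background.

Two distinct quantities come from the trace and they are deliberately not
the same number:

* **N**, the traced pixel count — the length of the radial sequence used by
  spicules, coarseness and lobulation;
* **C**, the Freeman chain length (axial step 1, diagonal step √2) — the
  perimeter entering circularity.

A pure pixel count cannot serve as a perimeter: for a rasterized disc the
8-thin boundary count is ≈ 0.89·2πR and the 4-thin count is ≈ 1.27·2πR, so
C²/S would come out 20% below 4π or 62% above it (the latter also scoring a
disc *worse* than a square, inverting the isoperimetric ordering the feature
exists to express). The chain length gives ≈ 1.10·2πR, keeps a square at
exactly 4s−4, and preserves disc < square < lobed ordering.

## Shape features

* **Circularity** C²/S. Continuous-limit 4π for a disc; measured ≈ 13.9 on
  rasterized discs of radius 30–80 (the ~10% excess is the known Freeman
  chain-length bias for smooth curves).
* **Height-to-width ratio**: inclusive pixel extents (max − min + 1) of the
  boundary's axis-aligned bounding box, consistent with the pixel-count
  semantics of S.
* **ALS**: a direct algebraic least-squares ellipse fit
  (`skimage.measure.EllipseModel`) to the boundary pixels; the long-axis
  angle is folded into [0, π/2] by the four-branch reflection map (θ; π−θ;
  θ−π; 2π−θ), which is π-periodic — an axis has no direction. Near-circular
  fits (a/b < 1.05) still report a value but carry an `als_low_confidence`
  flag, because orientation is ill-defined there.

## Margin features

The boundary is re-expressed as a clockwise polar sequence (rᵢ, θᵢ) about
the centroid; the pixel order of the trace is kept, so non-star-shaped
margins remain well-defined.

* **Spicules**: one-sided DFT magnitude spectrum of the radii with bin k at
  angular frequency ωₖ = 2πk/N. The statistic is Σ(ωₖ ≤ π/4) / Σ(π/4 < ωₖ ≤ π),
  DC included in the numerator — so the value scales with lesion radius, and
  a perfectly smooth boundary (zero high-frequency magnitude) returns an
  `inf` sentinel rather than raising: smooth lesions are legitimate inputs.
  The sentinel is excluded (and counted) at the statistics stage.
* **Coarseness**: mean absolute cyclic first difference of the radii, in
  pixels.
* **Indistinctness**: 3×3 Sobel gradient magnitude (replicate padding at the
  image border) summed over the margin band — the boundary pixel set dilated
  by a disc of radius `margin.band_width` (default 5 px; the band covers
  tissue just inside and outside the margin, and the value is reported ×10⁻⁶
  in feature tables). Blurring the margin strictly decreases it.
* **Lobulation**: cyclic median filter of frame 21 on the radii, then a
  least-squares *periodic* smoother — a trigonometric polynomial in
  t = i/N with harmonics 1..`poly_degree`/2 (20 coefficients beyond the
  constant at the default degree 20). The boundary is closed; an algebraic
  polynomial on the unwrapped coordinate produces Runge-type seam artifacts
  that systematically add a spurious extremum pair (planted k-lobe profiles
  then count 2k+2, failing for every k), while the periodic basis recovers
  2k for k = 2..8 in 20/20 noisy replicates. Extrema are counted on the
  cyclic sample grid with plateaus merged; variations below 0.5 px are
  treated as plateaus because rasterizing a smooth boundary leaves a
  staircase ripple measured at < 0.4 px after smoothing — so a clean disc
  counts 0 while real lobes (≥ ~1.5 px deep) are unaffected. A plain
  ellipse counts 4: its radial profile genuinely has four extrema.

## Calcifications

Pixels outside the mask are zeroed; the interior is binarized at
T = μ + α(max − μ) with α = 0.5 (midpoint between interior mean and maximum,
exposed as `calc.alpha`) — the count is therefore invariant to uniform
brightness shifts. The binary image is cleaned with a disc structuring
element, dilation-then-erosion by default (`calc.morph_order = "close"`,
with `"open"` available: the conventional speck remover; which of the two is
"right" is ambiguous, so both are one config key apart), restricted back to
the mask so dilation cannot leak outside the lesion. Components smaller than
`calc.min_blob_px` (default 4) are dropped and the rest counted at
8-connectivity.

## GLGCM texture

The grey level gradient co-occurrence matrix H(i,j) tallies interior pixels
by quantized grey level (L_s = 16 levels over the fixed range [0,255];
per-lesion min–max is available) and quantized Sobel gradient magnitude
(L_g = 16 levels over [0, interior max]); P = H/ΣH. Gradients are
normalized per lesion because absolute gradient scales depend on instrument
gain and are not comparable across machines.

* **Energy** Σ P², in (0,1], equal to 1 exactly when one cell holds all mass.
* **Entropy** of the grey marginal qᵢ = Σⱼ P(i,j), natural log, bounded by
  ln L_s = ln 16 ≈ 2.77. This is deliberately the *marginal* entropy (the
  inner sum sits inside the logarithm), not the joint entropy — the joint
  variant would be bounded by ln 256 instead.
* **Grey mean** Σ gᵢ qᵢ with gᵢ = (i−1)/(L_s−1) ∈ [0,1]; the raw level-index
  scale is available via `texture.gm_scale = "levels"`. The normalized scale
  keeps the value in [0,1] regardless of L_s.

## The phantom generator

Phantoms emulate exactly the image properties the features measure, nothing
more. The boundary is r(θ) = r₀·e(θ)·(1 + Σ aₖ cos(kθ + φₖ)) with e(θ) the
rotated-ellipse radial profile (semi-axes r₀√q and r₀/√q for axis ratio q);
Σ|aₖ| < 0.5 keeps it star-shaped. The interior is hypoechoic (mean 80 vs
exterior 160 by default), optionally split into concentric *equal-area*
intensity bands spaced 16 grey levels apart — equal areas (quantile-banded
boundary distance) and fixed per-band spacing make heterogeneity grow
monotonically in the band count by construction; a fixed total span does
not, because the quantized marginal saturates. Speckle is multiplicative
Gaussian (σ = 0.08), clipped to [0,255] — a deliberate simplification over
Rayleigh/log-compressed acoustic speckle, sufficient because the features
depend only on first- and second-order intensity statistics. Margin blur
blends a Gaussian-filtered copy near the boundary with a distance-based
weight. Calcifications are intensity-250 discs rejection-sampled with
pairwise separation ≥ 4·radius and a 2 px standoff from the margin, which
makes the planted count identifiable by construction. One RNG seeded from
`spec.seed` drives everything: identical specs are bit-identical on one
platform (cross-platform, feature values agree to ~1e−6 but pixel equality
is not guaranteed).

What phantoms do **not** model: beamforming, attenuation, posterior acoustic
features, shadowing, real organ backgrounds, observer variability in
contouring. Passing recovery tests therefore demonstrates that the feature
implementations measure what they claim on images with known answers — not
that the features separate real benign from malignant lesions.

### Cohort profiles

`make_cohort` draws per-lesion specs from group distributions. The default
effect profile plants the directions the feature set is meant to detect:
the malignant arm gets higher-order, larger-amplitude boundary harmonics
(more lobulation), fewer planted calcifications, smaller orientation angles
(half-normal scale 8° vs 17°, folded means ≈ 6° vs 14°), and fewer interior
bands (lower texture entropy). The zero-effect profile draws both arms from
the benign distributions and exists for type-I-error calibration.

## Statistics

Group description uses sample mean and SD (n−1). The comparison is the
two-independent-samples t-test, pooled-variance Student by default (the
classical reading of that name; Welch via `--welch` or
`stats.variant = "welch"`), two-sided p, significance at 0.05, with no
multiple-testing correction — eleven uncorrected tests. Zero-variance
degeneracies are resolved explicitly (equal means → t = 0, p = 1; unequal →
p = 0, flagged). Overflow spicule sentinels are excluded per feature with
exclusion counts reported. Pathology-table percentages are rounded
half-to-even to one decimal; totals are integer sums.

## Problem sizes and numerical choices

Calibration tests use 200 zero-effect cohorts of 8+8 lesions (≥ 2000
feature-level tests) and 100 default-profile cohorts of 20+20 for power —
sizes chosen so the binomial standard error of the estimated rates is well
inside the asserted bands. Phantom canvases are 112–180 px with r₀ 25–50 px.
Ellipse fits use the direct algebraic method (no iteration); the
trigonometric smoother solves a well-conditioned least-squares system (the
periodic basis is orthogonal on the uniform grid); degenerate inputs
(empty masks, collinear boundaries, centroid-on-boundary, sub-8×8 images)
raise typed validation errors rather than propagating NaNs.

## Known limitations

* Features are computed on the stored contour; no sensitivity analysis to
  contour placement is included, although manual contouring is the dominant
  practical error source.
* The spicule ratio includes the DC term, so it scales with lesion size;
  comparisons are only meaningful within one resolution setting.
* Lobulation counts undulations of the radial profile about the centroid;
  deeply non-star-shaped margins alias through the pixel-order fallback.
* The calcification stage counts blobs only; size and shape of
  calcifications are not characterized.
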