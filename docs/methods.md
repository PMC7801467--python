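# Methods

This note documents the measurement model behind `costripe`: what each
stage computes, the tunable parameters and their defaults, what the
synthetic scenes emulate (and what they deliberately do not), and the
numerical choices that fix otherwise-ambiguous behavior.

## Coordinate and intensity conventions

Images are 2D grids with 0-based indices, `x` = column, `y` = row, and a
pixel-center convention: physical position (µm) = index × `um_per_px`.
Angles are counter-clockwise with 0° along +x and +y pointing from larger
to smaller row indices. CO maps follow the darker-is-blob convention
(heavier staining absorbs more light). Every map carries a validity mask;
invalid pixels (out-of-domain resampling, exclusion masks) never enter any
bin average or normalization.

## Preprocessing and segmentation

`preprocess_co` applies three steps:

1. a Gaussian low-pass (`lowpass_sigma_um`, default 30 µm — below the blob
   radius, enough to suppress pixel noise without moving blob borders);
2. division by the large-scale staining background, estimated by a
   normalized Gaussian convolution (`background_sigma_um`, default half the
   equalization window). This removes smooth multiplicative staining
   gradients;
3. bell-shaped local histogram equalization: each pixel's rank within a
   sliding square window (`eq_window_um`) is mapped through the quantile
   function of a truncated normal centered mid-scale (mean 0.5, sd 1/6 of
   the scale, truncated to [0, 1]), so every local histogram is
   redistributed around the center of the intensity scale while the local
   dark-to-bright ordering is preserved.

The equalization window trades flattening power against contour fidelity:
small windows remove shorter-scale inhomogeneity but let local blob-density
fluctuations reorder pixels across windows, which distorts the threshold
contour. The pipeline default is six times the blob spacing: on synthetic
scenes this keeps the intersection-over-union between segmented and planted
masks at ~0.96 while the background division removes the shading. Since
thresholding depends only on ranks, the bell target changes the displayed
image but not the segmentation.

`segment_blobs` thresholds at the `dark_fraction` (default 0.33) quantile
of valid-pixel intensities, defined as the order statistic of rank
`floor(dark_fraction * N)`; pixels strictly below it are blob pixels, so
with all-distinct intensities exactly `floor(0.33 N)` pixels qualify and
threshold ties are excluded. Connected components (8-connectivity) smaller
than `min_area_um2` (default: a circle one-third the target blob diameter)
revert to interblob.

Blob centers are each blob's global intensity minimum; when
`multi_center_min_spacing_um` is given (pipeline default 0.8 × spacing),
additional local minima at least that far apart and darker than the blob's
25th intensity percentile become extra centers, capturing the multiple CO
peaks of elongated blobs. Interblob centers are the brightest valid
non-blob pixels on the straight segment between adjacent blob centers;
adjacency is the Delaunay triangulation of all centers with edges longer
than 1.4 × the median removed. The cutoff matters: in quasi-hexagonal
mosaics the triangulation occasionally flips a rhombus diagonal, producing
edges between next-nearest neighbors (~1.7 × spacing) whose midpoints would
inflate the B_ctr–I_ctr distance by ~10%. Manual center corrections are
applied from a CSV table rather than interactively.

## ROI sizing, heatmaps and radial profiles

`compute_roi_size` casts rays at `angle_step_deg` (default 20°) increments
from every blob center. Two geometries are supported: distance to the
first crossing of an interblob centerline mask, or (the pipeline default)
the nearest adjacent interblob-center point assigned to each ray heading
within half the angular step. The point-based rule is used because each
detected interblob center is tied to the blob pair that produced it, so a
ray measures the distance to *its own* interblob boundary; the mean
first-crossing distance of a hexagonal cell boundary exceeds the
center-to-edge distance by the secant factor (~6%), which would misplace
the profile's endpoint relative to the detected interblob centers. Rays
that hit nothing are dropped; the per-blob means are averaged into the
grand-average B_ctr–I_ctr distance, and the ROI side is `roi_multiplier`
(default 2) times that, rounded to an odd pixel count so the blob center
occupies the central pixel.

`accumulate_heatmap` sums the intensity in the ROI centered on every used
blob center and divides by the maximum. Centers whose ROI leaves the image
or touches invalid pixels are excluded entirely (not NaN-padded), keeping
the normalization unbiased; the used count is recorded. A blob is "used"
for a fluorescence layer when its ROI mean exceeds the field background,
estimated robustly as median + 2 × MAD of all valid fluorescence pixels —
which presumes the labeled field covers a minority of the section, true
for single-injection material and for the synthetic default geometry.

`radial_profile` evaluates a rectangle of width `window_width_um` (default
200 µm) from the heatmap center to the radius `side/2` at each heading,
picks the heading with the highest mean (ties to the smallest angle; a
1e-6-µm boundary tolerance keeps rasterization stable at cardinal
headings), and splits the chosen window into `n_profile_bins` (default 20)
equal bins of *distance from the blob center*, normalized to a maximum
of 1. A pixel belongs to the window if its center lies inside the rotated
rectangle; window pixels beyond the interblob-center radius (possible in
the window's far corners) are excluded from binning. Distance from the
center — rather than the projection onto the window axis — is used as the
radial coordinate because projection mixes true radii across the window's
200-µm width and displaces the profile peak inward by roughly ⟨v²⟩/2r
(~7 µm at the default geometry), enough to move the CO control's peak out
of the last bin. Bin centers sit at (k − 0.5)/20. CO and fluorescence
profiles choose their windows independently. Cubic summaries are ordinary
least squares on (bin center, bin value).

`population_heatmap` rescales per-case heatmaps to the largest side with
bilinear interpolation, sums pixelwise and re-normalizes; sources (and
layers, when set) must match.

## Laminar profiles

The densest 500-µm column maximizes total valid label between the pia and
white-matter polylines over all horizontal positions (ties to the leftmost
position). Depth is the fractional position between the pia and
white-matter rows interpolated at each column; for flat synthetic sections
this reduces to the row coordinate. The column is split into 100 equal
depth bins (`[(k−1)/100, k/100)`, last bin closed); bin values are mean
valid-pixel intensities normalized to a maximum of 1, bins with no valid
pixel are NaN and excluded downstream. Case profiles are per-bin means
over that case's section profiles, re-normalized. Layer membership is by
bin-center depth against half-open `[lower, upper)` layer bands. Group
datasets pool each case's section-averaged bins within a layer across the
cases of a stripe group. Any section count ≥ 1 per case is accepted (the
classic design uses 3); the count is recorded.

## Registration

Thin-plate-spline warps use the kernel `U(r) = r² log r` (`U(0) = 0`) with
the standard bordered linear system; `regularization_lambda` (default 0,
an interpolating spline, matching interactive landmark tools) is added to
the kernel diagonal. Landmark configurations with fewer than 3 points or a
collinear source set are rejected. Stacks are composed by function
chaining of pairwise warps — never re-fitted — and each section carries
both directions: points map *to* the reference frame, images are resampled
*from* it (pull-back sampling with nearest or bilinear interpolation;
out-of-domain or invalid-support pixels are flagged invalid).

## Intrinsic-imaging maps

Single-condition frames (already trial-averaged; a helper averages trials
ignoring flagged bad ones) are corrected by baseline subtraction, baseline
division, or division by the cocktail blank (the mean across all condition
frames). Division by zero-valued pixels flags them invalid. Difference
maps are plain subtractions, exactly antisymmetric in the condition pair;
for spatial-frequency stacks the convention is low minus high. Which of
the three corrections gives the cleanest maps is an experimenter judgment;
none is auto-selected.

## Statistics

Mann–Whitney U uses midranks for ties; the p-value is exact (full
enumeration) for tie-free samples with n₁ + n₂ ≤ 16, otherwise a normal
approximation with tie and continuity corrections. Kruskal–Wallis reports
the tie-corrected H; pairwise post-hoc contrasts are two-group
Kruskal–Wallis tests (equivalent to Wilcoxon rank-sum) evaluated against
the Bonferroni-corrected per-comparison α = family α / number of pairs.
With three stripe types at family-wise 0.05 this is 0.05/3, displayed as
0.017; significance checks use the unrounded value. Dunn's z-tests on the
joint ranking are available as an alternative post-hoc. All tests are
two-sided by default. At n = 20 per group the χ²-approximated pairwise
test is slightly conservative: its true null rejection rate is ~0.0145 at
nominal 0.0167 (measured over 10⁴ null cohorts), a property of the
discrete rank statistic worth remembering when interpreting marginal
p-values.

High-intensity bins are those with normalized value strictly above
`high_bin_threshold` (default 0.70); their bin-center locations form the
per-layer datasets compared across stripe types, layer by layer and pooled.

## Synthetic scenes: what they emulate, and what they do not

`generate_co_map` plants a jittered hexagonal lattice (jitter = per-axis
uniform displacement with full spread `lattice_jitter_frac` × spacing,
keeping mean nearest-neighbor distance within ~10% of the spacing for
spreads < 0.2). Each blob is an inverted Gaussian dip (σ = mask radius /
1.5) whose planted mask is the disk at the equivalent-area radius but
whose intensity support extends to 3 × that radius, so interblob tissue is
graded — brightest farthest from all blobs — as in real CO staining; a
hard truncation at the mask radius would make all interblob pixels
identical and the brightest-pixel interblob-center rule degenerate. With
probability `elongated_blob_prob` a site merges with a nearest neighbor
into a capsule-shaped blob with two planted intensity minima. The lattice
overhangs the image border so the mosaic covers the field to the edge
(clipped border blobs), as in a blob-filled map crop; ground truth lists
only in-image peaks. Multiplicative shading is a random-orientation linear
ramp; noise is additive Gaussian. The interblob centerline ground truth is
the Voronoi boundary of blob groups restricted to non-blob pixels.

`generate_label_field` drops `n_patches` Gaussian patches with per-pixel
placement weight ρ on blob pixels and 1 − ρ elsewhere, so ρ = 0.5 is
genuinely indifferent (blob mass share = blob area fraction), ρ = 1 purely
blob-seeking. The compartment coin and both pixel draws occupy fixed
positions in the random stream, making the blob-mass share monotone in ρ
at fixed seed. Defaults — 80 patches of σ = 100 µm (FWHM ≈ 235 µm,
a realistic feedback-patch scale relative to ~300-µm blobs) confined to a
centered 2.4-mm zone of the 3.6-mm field — represent a dense terminal
field from a single injection occupying a minority of the section, which
the median-based background estimate requires.

Default scene geometry: 360 × 360 px at 10 µm/px, blob spacing 450 µm,
target diameter 300 µm, jitter 0.1, contrast 0.5, shading 0.15, noise
0.02 — roughly 35 analysable blobs per scene, a realistic single-case
field at desk-scale cost (~0.8 s per scene).

What the scenes do **not** emulate: real histology's vascular artifacts,
tears and folds, nonstationary blob geometry across eccentricity, tracer
uptake gradients, optical vignetting beyond a linear ramp, or correlated
noise. Passing the recovery suite therefore demonstrates that the
measurement chain is correct and unbiased under the assumed statistical
structure, not that it is robust to every failure mode of real sections —
the validity mask and manual-correction hooks exist for exactly those
cases.

`generate_laminar_section` renders flat sections with per-layer step
amplitudes; nominal layer bands (fractions of pia-to-white-matter depth)
are L1 0–0.07, L2/3 0.07–0.35, L4A 0.35–0.40, L4B 0.40–0.50, L4C
0.50–0.64, L5 0.64–0.78, L6 0.78–1, schematic values in the range of
classic macaque V1 measurements. `generate_oi_conditions` adds a planted
response map to a baseline with Gaussian noise. `generate_landmark_pair`
draws non-collinear source points (resampling degenerate draws from the
same stream) and applies the planted warp exactly.

## Determinism and reproducibility

All randomness flows through explicit `numpy.random.Generator` instances
seeded per call; no global state. Report bundles contain no timestamps,
floats are rounded to 9 decimals before serialization, and JSON keys are
sorted, so rerunning an identical configuration reproduces every artifact
byte for byte; each summary carries the seed and a configuration hash.

## Known limitations

* The rotated-window selection is evaluated on the pixel lattice, so exact
  rotation equivariance holds only for rotations that are multiples of the
  angular step, and window means for radially symmetric inputs agree only
  to rasterization accuracy (~0.5%).
* The bell-equalization window couples flattening scale and contour
  fidelity; heavily inhomogeneous staining at scales below ~2 blob
  spacings cannot be flattened without some contour distortion.
* The background estimate for blob selection (median + 2 × MAD) fails if
  labeled tissue covers most of the field; supply an explicit exclusion
  mask or restrict the analysis region in that case.
* Laminar depth uses per-column linear interpolation between the pia and
  white-matter polylines — adequate for gently curved columns, not for
  strongly folded cortex.
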