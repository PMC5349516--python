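# Methods

This note documents the models, numerical choices and validation
strategy behind `osteotrace`, and what the synthetic phantoms do and do
not establish about real μCT data.

## Coordinate conventions and units

Stacks are indexed `voxels[z, y, x]` with 0-based voxel indices; (x, y)
are in-slice coordinates and z the slice index. Voxels are isotropic;
the default edge length is 14.599 μm, the resolution of the in-vivo
paw scans this pipeline targets. All exported physical quantities are in
mm (radii, thicknesses, the fit intercept m); CTG and CTI are
dimensionless.

## Filter bank

The texture bank follows the classic receptive-field design: Gabor
quadrature pairs plus isotropic difference-of-Gaussians.

* A Gabor kernel is `exp(-(x²+y²)/2σ²) · cos(2πω(x cosθ + y sinθ) + φ)`,
  evaluated on an odd grid covering ±3σ, then mean-subtracted and
  L2-normalized. The circular window (σ_x = σ_y = σ) keeps orientation
  selectivity in the carrier only.
* A DoG kernel is the difference of two concentric Gaussians, each
  discretely normalized to unit sum, so the kernel sums to zero exactly
  and has a positive center (σ_center < σ_surround).
* Defaults: 3 octave-spaced frequencies {0.05, 0.1, 0.2} cycles/px,
  6 orientations {0, π/6, π/3, π/2, 2π/3, 5π/6}, phases {0, π/2}
  (36 Gabors), and 4 DoG pairs with (σ_center, σ_surround) =
  {0.075, 0.125}, {0.125, 0.175}, {0.175, 0.225}, {0.225, 0.275} in
  units of a base support of 31 px (i.e. pixel sigmas 2.3–8.5 px).
  The Gabor window is tied to frequency by σ = C/ω with C chosen so the
  widest Gabor equals the widest DoG surround, putting both families on
  one scale range. The exact frequencies and the base support are open
  design parameters exposed in the config; nothing downstream assumes
  their specific values.

Zero-mean (DC-free) kernels make constant regions map to zero response,
which yields the key operational property: segmentation is invariant to
affine intensity rescaling of the input (verified exactly in the tests),
so the method transfers across scans without threshold tuning.

## Texture segmentation

Each slice is mirror-padded by half the largest kernel support and
convolved with all kernels in the Fourier domain (a shared image FFT;
equivalence with brute-force spatial convolution is asserted to 1e−8 in
the tests). Each pixel's N_F-vector of responses is clustered with
k-means++ (k = 2, Euclidean metric on raw responses, 10 restarts, fixed
seed recorded in outputs; scikit-learn implementation). The cluster
whose pixels have the higher mean *original* intensity is labeled bone —
bone is the radiodense phase. Slices are clustered independently by
default (a pooled whole-stack mode exists behind a flag); per-slice
clustering keeps each slice reproducible in isolation.

A baseline segmenter (global Otsu or fixed threshold + morphological
opening with a disc) is included for comparison. On phantoms of two
adjacent bones bridged by diffuse soft tissue, the global threshold
captures the bridge and merges the bones into one connected component,
while the texture clustering — responding to local structure, not
absolute intensity — leaves the bridge in the background and separates
them. This is the failure mode of thresholding that motivates the
texture approach.

### Known limitation: sub-pixel edge bias

The k-means decision boundary sits where a pixel's response vector is
equidistant from the two cluster centers, not exactly at the 50%
intensity crossing of the physical edge. On phantoms this places the
segmented boundary within a fraction of a pixel of the true edge
(stack Dice ≈ 0.96–0.99), but the residual offset depends weakly on the
local ring/cavity scale. Since the true radii of a metatarsal-scale
phantom vary by only ~1 px end-to-end, this scale-dependent bias
attenuates the *fitted* thickness gradient of a segmentation-derived
mask even when Dice and CTI are excellent (in our tapered phantom the
full-pipeline slope came out at roughly half the generated value, while
CTI was within 1%). Two consequences:

* geometric-accuracy claims (CTG/CTI parameter recovery, orientation
  independence) are validated on ground-truth masks, isolating the
  measurement chain (tracking → orthogonalization → ray casting → fit)
  from segmentation;
* CTG values from segmented data should only be compared across scans
  segmented with the identical configuration — as in a longitudinal
  study where all time points run through the same pipeline — because
  the attenuation is consistent, preserving ordering and contrasts.

## Bone tracking

Connected components use 8-connectivity per slice. From the seeded
region, the successor in the next slice is chosen among regions whose
footprint overlaps the previous region's footprint (the "shadow" is
defined as non-zero pixel overlap), minimizing the absolute area
difference; ties fall back to larger overlap, then smaller centroid
displacement. Tracking runs in both directions from the seed slice and
is confined to the slice interval corresponding to 0.75–3.5 mm above the
joint — below ~0.75 mm the spongy bone has no marrow cavity and the
cortical thickness is undefined. A slice with no overlapping candidate
truncates the track with a warning rather than failing. The per-slice
centers of mass form the centerline.

## Orthogonal resampling

The centerline's in-plane coordinates are smoothed by a moving average
(window 5 slices) and the local tangent at slice i is the symmetric
difference `normalize((x_{i+w} − x_{i−w}, y_{i+w} − y_{i−w}, 2w))` with
half-window w = 5, clamped one-sided at the ends. Both windows assume
only that the bone is approximately straight over ~10 slices (~0.15 mm).

The local frame takes e_y′ as the normalized rotation axis e_z × e_z′
and e_x′ = e_y′ × e_z′, giving a right-handed orthonormal basis whose
forward/inverse transfer matrices are transposes of each other; when the
tangent is numerically parallel to the scan axis (‖e_z × e_z′‖ < 1e−8)
the identity frame is used. Cross-sections are sampled on a square grid
in the (x′, y′) plane at the native voxel spacing via trilinear
interpolation; samples outside the volume read as background. Binary
masks are interpolated as 0/1 fields and thresholded at 0.5, avoiding
the stair-step bias of nearest-neighbor lookup. The longitudinal
coordinate ξ of a section is the arc length along the smoothed
centerline from the joint slice (extrapolated to the joint with the
initial per-slice increment), which remains meaningful for curved bones.

## Radii, CTG and CTI

Rays from the section's foreground center of mass sample the
(interpolated) mask field at 0.25 px steps at 25 uniform angles — a
count matched to the typical inner-perimeter circumference of 15–50 px.
The inner radius is the first background→foreground crossing, the outer
radius the last foreground→background crossing, both sub-pixel by linear
interpolation between samples; on a binarized mask this pins each
boundary to within half a pixel (the pixelation limit). A ray is valid
only if the center pixel itself is background (a marrow cavity exists)
and both crossings occur; solid sections (spongy bone) yield no valid
rays and drop out. Rows of Ψ(ξ, θ) with fewer than 13 of 25 valid rays
are excluded from the angular average.

CTG is the slope of the ordinary least-squares line through
(ξ, Ψ̄(ξ)), computed over the 0.75–3.5 mm window; with both axes in mm
the slope is dimensionless and thinning near the joint (ξ small) makes
it positive. CTI is implemented as the per-ray relative thickness
(r_out − r_in)/r_out averaged over all valid (ξ, θ): the classical
cortical index, dimensionless and bounded by 1 (a diameter-based variant
is available behind a config switch; the two coincide for circularly
symmetric sections).

## Synthetic phantoms

A phantom is a tube around a straight, tilted or gently curved axis with
linear radius functions r_in(ξ), r_out(ξ), so the true gradient
(slope of r_out − r_in) and the true CTI (trapezoid-rule mean of
1 − r_in/r_out over the measurement window) are known in closed form.
Voxelization measures each voxel's distance to the local tangent line of
the axis at its slice — exact for straight/tilted axes and accurate to
O(curvature·r²) for the curved presets — with 3×3 in-plane subpixel
sampling so edges carry partial-volume fractions. Intensities follow the
ordering of real paw scans (background < soft tissue < marrow < bone;
defaults 20/45/70/200 in arbitrary units), then in-plane Gaussian blur
(σ = 0.8 px, a point-spread stand-in) and additive Gaussian noise
(σ = 8, ~4% of the bone-background contrast) are applied; ground truth
is taken before degradation and is independent of the noise seed.

Default geometry mirrors the target scans: 14.599 μm voxels, outer
radius 0.30 mm (~20 px), inner radius 0.18 mm at the joint, 250 slices
covering the full 0.75–3.5 mm measurement window (~188 measured
sections). The tapered presets sweep true gradients {0, 0.005, 0.010,
0.015}, bracketing the healthy-to-arthritic range observed in vivo
(≈0.006–0.014); tilted (15°, 25°) and curved presets probe orientation
independence; the `adjacent_bones_bridged` preset places two tubes
13 px apart joined by a heavily smoothed soft-tissue ridge (intensities
20/120/140/200), constructed so a global Otsu threshold includes the
bridge while its weak gradients leave it texture-background. Diffuse
bridges are the physically motivated choice: cartilage and inflamed
tissue have soft boundaries, while bone edges are sharp.

What the phantoms do **not** emulate: trabecular texture inside the
marrow, beam hardening, reconstruction streaks, anisotropic PSFs, or
anatomical cross-section shapes (sections are circular). Passing
phantom tests therefore demonstrates the correctness of the geometry and
measurement chain and the qualitative segmentation claims, not
segmentation accuracy on arbitrary real scans.

## Numerical and design details

* FFT convolution uses symmetric (mirror) padding by half the largest
  kernel support, eliminating wrap-around artifacts.
* k-means degenerate input (all feature vectors identical) returns an
  all-background mask with a warning rather than failing.
* Tie-breaks in tracking are deterministic (area → overlap → centroid
  displacement), and every stage is a pure function of its inputs and
  recorded seeds: repeated runs produce byte-identical CSVs.
* The resampling window half-extent defaults to 2.5× the tracked
  region's equivalent-area radius, generously covering the outer
  perimeter; out-of-window content reads as background.
* Statistical analysis of exported metrics (mixed-effect models across
  animals/time) is deliberately out of scope: the CSVs are tidy inputs
  for R/lme4 or statsmodels.
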