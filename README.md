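# osteotrace

Quantifying cortical-bone degradation in longitudinal μCT of small-animal
arthritis models.

Experimental arthritis (e.g. G6PI-induced arthritis in mice) erodes the
cortical shell of the metatarsals, most strongly near the
metatarsophalangeal joints. `osteotrace` turns a 3D μCT stack of a paw
plus two manual clicks per bone (one point inside the bone, the slice of
the joint) into quantitative cortical-profile measurements that are
independent of how the animal lay in the scanner:

1. **Texture segmentation** — every slice is convolved with a bank of
   N<sub>F</sub> = 40 filters (36 Gabor quadrature pairs: 3 spatial
   frequencies × 6 orientations × phases φ ∈ {0, π/2}; plus 4
   difference-of-Gaussians with a positive center), and the pixels are
   split into bone/background by k-means++ with k = 2 on the response
   vectors. Because the kernels are zero-mean, the segmentation is
   invariant to affine intensity rescaling and needs no threshold tuning;
   it also separates adjacent bones bridged by soft tissue that defeat
   global thresholding.
2. **Bone tracking** — from the seeded slice, the bone's connected region
   is followed slice-to-slice by matching the candidate region with the
   smallest area difference among those lying in the previous region's
   shadow, giving a per-slice centerline (x<sub>i</sub>, y<sub>i</sub>, i).
3. **Orthogonal resampling** — at each centerline position a local
   orthonormal frame (**e**<sub>x′</sub>, **e**<sub>y′</sub>,
   **e**<sub>z′</sub>) is built from the local tangent, and cross-sections
   are resampled perpendicular to the bone axis by trilinear interpolation.
4. **Cortical metrics** — in cylindrical coordinates (r, θ, z′) centered
   on each section's center of mass, rays at N<sub>θ</sub> = 25 angles
   measure the inner and outer perimeter radii; the cortical thickness is
   Ψ(ξ, θ) = r<sub>out</sub>(ξ, θ) − r<sub>in</sub>(ξ, θ), with ξ the
   arc-length distance above the joint (measured over 0.75–3.5 mm).
   Two scalars summarize a bone:
   * **CTG** (cortical thickness gradient): the dimensionless slope *k* of
     the least-squares line Ψ̄(ξ) ≈ kξ + m fitted to the angular average —
     thinning concentrated near the joint raises *k*;
   * **CTI** (cortical thickness index): the mean of
     (r<sub>out</sub> − r<sub>in</sub>)/r<sub>out</sub> over all valid
     (ξ, θ) — overall relative shell thickness, in (0, 1].

A synthetic-phantom module generates tubular "metatarsals" (bright
cortical ring, darker marrow, soft-tissue bridges, blur, noise; straight,
tilted or curved axes; linear radius profiles) with closed-form ground
truth, so the whole pipeline is validated without animal data.

## Worked example

Generate an "arthritic" phantom whose cortex thins toward the joint with
a true gradient of 0.010, then measure it:

```sh
$ osteotrace phantom --preset tapered_ctg10e-3 --out phantom_out
wrote tapered_ctg10e-3 to phantom_out (ctg_true=0.0100, cti_true=0.4708)

$ osteotrace measure phantom_out/truth_mask.tif --seeds phantom_out/seeds.yaml \
      --out-dir measured --voxel-size-um 14.599
bone_id     ctg  intercept_mm      cti  n_slices  fit_rms_mm      config_hash  kmeans_seed
phantom 0.01008      0.119197 0.470055       188     0.00094 89a708199fb3e25f            0
```

The recovered gradient (`ctg` 0.01008) matches the phantom's true slope
0.010 to within 1%, and the thickness index (`cti` 0.470) matches the
analytic value 0.4708; 188 orthogonal cross-sections entered the fit with
a residual RMS below 1 μm. `measured/profile_phantom.csv` holds the full
Ψ(ξ, θ) profile in tidy long format (`xi_mm, theta_rad, r_in_mm,
r_out_mm, psi_mm, valid`) ready for external mixed-model statistics; all
CSVs carry the configuration hash and clustering seed for provenance.

For grayscale stacks, `osteotrace run <stack> --seeds <seeds.yaml>
--out-dir <dir>` performs texture segmentation first and then the same
tracking and measurement; `osteotrace segment` / `track` expose the
individual stages.

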