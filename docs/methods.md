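# Methods

This note documents the models, estimators and numerical choices behind
`pulmovasc`, in the order data flows through the pipeline.

## Coordinate conventions

All 3D quantities live in physical micrometres, `(z, y, x)` order, with voxel
`(i, j, k)` centred at `((i+0.5)dz, (j+0.5)dy, (k+0.5)dx)`. Multiphoton
stacks are strongly anisotropic (z-steps of 2.2–13.2 μm against in-plane
pixels of 1.13–4.54 μm), so voxel-unit lengths are meaningless; every length
in this package — edge lengths, skeleton polylines, dilation radii, distance
transforms — is computed with the per-axis spacing.

## The synthetic lung (`synthdata`)

The generator emulates a cleared-lung multiphoton stack well enough to give
every estimator a non-trivial, ground-truthed input. It is **not** an optics
simulation: there is no PSF, no depth attenuation, no scattering (see
*Limitations*).

**Geometry.** The lung boundary is an axis-aligned ellipsoid with semi-axes
0.42× the volume's physical extent; the hilum sits on its −y surface. From a
root node at the hilum, `n_root_vessels` (default 2) trees grow by recursive
bifurcation for `branch_generations` (default 4) generations: each branch
spawns two children rotated ±`branch_angle_spread`/2 (default 40°, jittered)
about a random perpendicular axis, with segment length ×0.72 and radius
×`taper_ratio` (default 0.8, root radius 8 μm) per generation. Segments are
shortened to stay inside a growth envelope at 0.7× the boundary — baseline
arteries stop short of the pleura — and additionally to reserve headroom so
that later peripheral elongation (up to a factor of 1.5) cannot leave the
lung; factors above 1.5 raise the per-tip boundary error rather than being
clipped silently.

**Remodeling.** Two knobs reproduce the qualitative remodeling of the
disease models:

* *Peripheral elongation*: terminal tips are moved to
  `hilum + f·(tip − hilum)` with `f = elongation_factor`.
* *Sprouting*: `n_sprouts` neovessel edges (radius 3.5 μm) are attached to
  terminal baseline tips, lengths drawn from a truncated normal (>0, via the
  inverse CDF so the draw count is seed-stable; default 45 ± 10 μm).
  Sprout placement spreads over the tips and picks, from a short candidate
  list of outward-then-tangential directions, the first whose tube clears all
  existing vessels by > 2 μm (segment–segment distance); sprouts that fused
  with the existing tree would make the recorded ground truth unmeasurable
  in principle, not merely hard to estimate.

The presets differ only in these two knobs — normoxia (0, 1.0),
Sugen+hypoxia (4, 1.05), hypoxia (20, 1.35) — magnitudes chosen once to
preserve the experimental ordering Nx < SuHx < Hx in angiogenic burden; no
absolute sprout counts are claimed for the biology.

**Rasterization.** Each edge is painted as a capsule (distance-to-segment
test in μm over the edge's bounding box; brute force is adequate at the
default 80×160×160 grid). The EC channel fills tubes; the SMA channel paints
an annular shell of thickness `wall_thickness_fraction × radius` (default
0.3) around **baseline** edges only — neovessels are unmuscularized. Noise
follows the standard fluorescence model, applied after geometry: Poisson
shot noise on signal (scale 1.0), then a constant background (10) plus
Gaussian read noise (σ = 3), clipped to the bit depth (8 by default).

**Determinism.** One `numpy` generator seeded by `SynthParams.seed` drives
tree growth; rasterization noise uses `(seed, channel)` so channels are
independent but reproducible. Identical parameters give bit-identical
volumes. A practical corollary used throughout the tests: regenerating with
`n_sprouts=0` and the same seed yields exactly the baseline tree of the
sprouted lung, because sprout draws happen after growth.

**Phantoms.** `make_cylinder_volume` paints a flat-capped cylinder (so the
analytic volume πr²L and centerline length L hold exactly) centred on a
voxel centre. The centring matters: a tube whose cross-section is
even-symmetric about a voxel *boundary* has no centre voxel, and 3D thinning
annihilates such configurations entirely. Oblique vessels — i.e. everything
the tree generator produces — never hit this degeneracy, but axis-aligned
phantoms must avoid it. `make_annulus_image` is the 2D wall-morphometry
phantom.

## Density (`density`)

Binarization is Otsu's criterion on the ROI histogram by default (the
threshold is always reported alongside results); a fixed threshold is
available. The comparison is strict (`intensity > t`), so an all-background
volume maps to an empty mask, and a constant volume raises under Otsu rather
than returning an arbitrary threshold. Density is voxel counting:
`foreground/roi` exactly, plus `foreground × voxel volume` in μm³. Per-slice
area integration and voxel counting are proportional under fixed spacing;
voxel counting was chosen. The ROI defaults to the whole grid.

## Skeletons and indices (`skeleton`)

`skeletonize_mask` thins the mask (Lee's 3D topological thinning via
scikit-image), drops components under 5 voxels, links centerline voxels by
26-connectivity, and compresses maximal paths between junction/terminal
voxels into branches. Cleaning applies two standard rules to a fixed point,
because spur removal and chain splicing interact: terminal branches are
pruned when shorter than 3 centerline voxels **or** than 1.5× their mean
tube radius (thinning artifacts scale with tube thickness; genuine side
branches extend beyond the parent tube), and pass-through nodes left by
pruning are spliced. Branch length is the polyline length of voxel centres
in μm after a 5-point moving-average smoothing of interior points
(endpoints pinned), which suppresses the stair-step overestimation of
oblique centerlines. Thinning also retracts free ends by up to one tube
radius, so each terminal branch is extended along its end tangent until the
ray exits the mask (bounded by twice the local distance-transform radius).
With these corrections a 200 μm straight tube measures 199–201 μm at both
isotropic and anisotropic spacing. Per-branch mean radius comes from the
Euclidean distance transform sampled along the centerline.

**Neovessel classification.** The baseline (pre-exposure or lineage-label)
mask is dilated by 2 in-plane voxels (as a physical radius, ≈ 2.3 μm at the
20× geometry) to tolerate ~1-voxel registration jitter. Each branch polyline
is partitioned into runs inside/outside the dilated baseline (3-point median
filter on the inside flags kills single-voxel flicker) and the outside run
lengths are summed; boundary segments split evenly. Run-level rather than
whole-branch accounting is essential: a sprout growing out of a terminal
baseline tip *prolongs* that branch through a pass-through junction, and a
whole-branch majority vote would misassign either the sprout or its parent
wholesale. Branches still carry a `neovessel`/`baseline` label (< 50%
in-baseline by length) for reporting, and per-branch neovessel + baseline
lengths sum exactly to branch length. At zero noise the estimator recovers
generator truth to within ≈ 10% (slightly low: the dilated region absorbs
each sprout's first few μm), monotone in sprout count.

**Indices.**

* *Angiogenesis index* = total neovessel length / lung circumference. The
  normalization is scale-free (both scale linearly with the lung). The
  circumference is measured on the mid-axial outline: analytically (ellipse
  arc-length quadrature) when the ellipsoidal boundary descriptor is
  available, else from a 2D mask by marching-squares contour extraction with
  a 7-point circular smoothing of the contour before summing segment lengths
  (removing pixelation bias; a rasterized circle measures within 0.2% of
  2πr). Whether the original index counted sprout number or summed length is
  not settled; summed length is implemented, as that is what a length
  measurement on renders produces.
* *SMC elongation index* — defined **here** (the originating work delegates
  its formula to prior literature) as the 90th percentile over terminal
  skeleton nodes of d(hilum→node)/d(hilum→boundary exit along the same ray).
  It is bounded in [0, 1], scale-free, equals 0 when all termini sit at the
  hilum and →1 as termini reach the pleura, and responds monotonically to
  the generator's elongation factor. The 90th percentile (rather than max)
  makes it robust to the odd stray terminus; termini at the hilum itself
  contribute 0 by convention.

## Similarity (`similarity`)

The 2.5D pipeline compares volume renderings, not volumes: maximum-intensity
projections capture remodeling shape while sidestepping anisotropic
registration.

1. **Preprocess**: channels collapse by BT.601 luma weights
   (0.299, 0.587, 0.114); resize to 256×256 by exact block averaging when
   the source is an integer multiple, else area-weighted interpolation. A
   256² grayscale input passes through bit-identically.
2. **Detect**: scale-normalized determinant-of-Hessian responses
   (σ⁴·det H) over a ladder of 8 sigmas (base 1.6, half-octave steps, 4
   octaves), 3×3×3 local maxima across (scale, y, x) above threshold 1e-4.
   A second-order blob/ridge response suits tubular vasculature; a constant
   image yields an empty set (not an error). Keypoints are capped at 500 by
   response.
3. **Describe**: upright 256-bit BRIEF descriptors (patch 49, Gaussian
   σ = 2, fixed sampling pattern), so descriptors are comparable across
   images and runs. Border keypoints that cannot host a patch are dropped.
4. **Match**: symmetric mutual nearest neighbours by Hamming distance
   (`np.bitwise_count` on packed bits), ties toward the lower index; the
   pairing is one-to-one and symmetric in the two images, which the
   group-wise comparisons require. A Lowe ratio test is available
   (`matcher="bruteforce-ratio"`) but is not the default, as it adds a
   parameter without changing the orderings of interest.
5. **Score** = arithmetic mean of matched pair distances; lower = more
   similar; identical inputs score exactly 0. With no keypoints or no
   surviving pair the score is NaN with an explicit `undefined` flag — never
   silently 0, which would mean "identical". "Distance" is descriptor
   (Hamming) distance by default; the image-space reading (mean pixel
   displacement of matched pairs) is implemented behind
   `distance_metric="spatial"`, since unregistered renders of different
   animals make spatial displacement hard to interpret.

The whole pipeline is deterministic for fixed input and config. Behavioral
guarantees (identity, symmetry, locality, monotone degradation under the
graded perturbation series, equivalence to exhaustive-search matching) are
asserted in the test suite; no bit-exactness to any third-party detector is
claimed.

`perturb_projection` provides the graded degradation harness: level k
composes a k·1.5° rotation, an elastic warp from a Gaussian-smoothed random
displacement field of amplitude k, and 2k spurious tube segments —
deterministic in `(seed, level)`, pixel-identical at level 0, strictly
increasing mean absolute difference in k.

## Morphometry (`morphometry`)

`measure_annulus` segments the bright wall (Otsu unless given a threshold),
keeps the largest component, fills holes, and converts areas to
equivalent-circle diameters `d = 2√(A/π)` — robust to mild non-circularity.
Thickness is `(d_outer − d_inner)/2`; the percent formula then applies. The
diameter is the **external** diameter: with the printed formula
`[(t × 2)/d] × 100`, only the outer reading keeps the percentage ≤ 100 for
every geometrically possible annulus. A filled disk (no lumen) correctly
reports 100%. Size classification (`small_artery` vs `arteriole`) is a
diameter cutoff with **no default**: the anatomic criterion (terminal
bronchiole vs acinar level) has no universal diameter equivalent, so the
cutoff is an explicit analyst choice. Fulton's index is the exact ratio
RV/(LV+S), unit-free, positive weights enforced.

## Statistics (`stats`)

Student's (pooled-variance) t rather than Welch, two-sided, as the package's
convention for these designs; ANOVA F with (k−1, N−k) df; Tukey's HSD via
the studentized-range distribution for all pairs; Pearson's χ² on 2×2
positive/negative tables without continuity correction (Yates' behind a
flag). Missing values drop listwise with a reported count. Identities held
exactly and asserted numerically: F = t² on two groups (p equal), Tukey
adjusted p ≥ unprotected pairwise t p. Monte-Carlo calibration at n = 7 per
group (a typical small-animal arm size) puts the type-I error of the F
test, the Tukey family-wise test and the t test in [0.04, 0.06] at α = 0.05
over 2,000 null replicates, and power > 0.9 for a 2-SD shift at n = 7.
Whether vessels-within-mouse are independent units is the caller's problem:
the tests analyze whatever unit the input table provides.

## Problem sizes

Defaults were chosen at desk scale: 80×160×160 voxels at the 20× geometry
(≈ 176×181×181 μm lung), 5 paired lungs per arm for group comparisons,
3 lungs per condition for recovery studies, 2,000 Monte-Carlo replicates,
10 perturbation seeds × 5 levels for the degradation sweep. At these sizes
the full test suite runs in a few minutes on one CPU.

## Limitations

* The generator has no PSF, depth attenuation, vessel curvature within
  segments, or intensity heterogeneity; passing tests demonstrate estimator
  correctness on clean geometry plus shot/read noise, not performance on
  real cleared-lung stacks (where binarization quality will dominate).
* Baseline and post volumes are assumed pre-aligned (true by construction
  for synthetic data); there is no registration step.
* Neovessel ground truth becomes ill-defined if sprouts overlap existing
  vessels; the generator actively avoids such placements, and recovery
  error grows where avoidance is geometrically impossible (dense lungs,
  sprouts much longer than the peripheral free space).
* The skeleton length estimator is biased low by a few percent on thin
  (< 2-voxel-radius) tubes and undefined for masks whose cross-sections are
  even-symmetric about voxel boundaries (see *Phantoms*).
* Similarity scores saturate: beyond heavy degradation the mean Hamming
  distance plateaus near the unmatched-descriptor expectation, so the score
  discriminates best among moderately similar renders — which is its use
  case here.
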