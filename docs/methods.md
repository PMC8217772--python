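# Methods

This document describes the computational model implemented by `nudpa`, the
assumptions it makes, and the numerical choices behind each stage. Units and
defaults are stated for every parameter. The worked end-to-end example with
concrete numbers is in the README; this file explains *why* each stage is
built the way it is.

## 1. Problem setting

Dynamic small-animal PET of the rodent brain produces a 4-D image (frames ×
z × y × x) per animal and measurement state (e.g. control vs. lesion).
Regional quantification requires mapping an anatomical atlas — defined on a
high-resolution MRI grid — onto each PET acquisition, then reducing the
dynamic data to per-region scalar parameters that can be compared across
groups. The pipeline automates this chain:

1. preprocess the dynamic frames,
2. resample the MRI atlas to PET resolution with fractional (partial-volume)
   region membership,
3. segment a brain volume of interest (VOI) on each control image,
4. build a cohort PET template from the control images,
5. align every measurement (within subject, then to the template, then to
   the MRI/atlas frame),
6. quantify per-region uptake parameters on the original dynamic frames,
7. run nonparametric group statistics.

All stages are pure functions of (inputs, configuration, seed); a run
manifest records the configuration hash and seed so results can be
reproduced bit-for-bit.

## 2. Image model and conventions

* Volumes are stored as NumPy arrays in `(z, y, x)` axis order; dynamic
  images as `(t, z, y, x)`. Spacing is carried per axis in micrometres.
  NIfTI I/O converts from the file's `(x, y, z[, t])` order.
* A dynamic image carries a frame schedule, a list of `[start_s, end_s)`
  intervals. Quantification intervals must tile whole frames; partial
  frames are rejected at validation.
* Intensities are treated as activity concentrations (Bq/mL). Voxel volume
  in mL is `z_um * y_um * x_um * 1e-12`.

## 3. Preprocessing

* **Peripheral slice exclusion** (`n_peripheral_slices`, default 5): the
  first and last axial slices of a scanner's field of view carry elevated
  noise and are dropped, only when the volume keeps at least two interior
  slices afterwards.
* **Speckle removal**: the frame-summed image defines a binary foreground;
  a foreground voxel whose 26-connected neighbourhood contains fewer than 5
  foreground voxels is treated as an isolated annihilation event and zeroed
  in all frames. Neighbour counts are evaluated once on the original mask —
  the filter is a single pass, not iterated, so it cannot progressively
  erode genuine structures. The number of removed voxels is reported.
* **Group intensity factors**: per experimental group, each summed image is
  scaled by `max(group means) / own mean`, harmonising global intensity
  *within* a group while never shrinking an image's dynamic range. The
  factors feed only segmentation/registration work images; quantification
  always uses the original (unscaled) frames.

## 4. Atlas resampling

The atlas-to-PET scale factor is the rational `1 / round(PET in-plane
resolution / MRI resolution)`; e.g. 776 μm PET against 39 μm MRI gives
exactly 1/20, against 25 μm exactly 1/31. Keeping the factor as an exact
fraction avoids drift when the same factor is applied per axis.

Each atlas region is downsampled *as its own indicator volume* with
trilinear interpolation (`grid_mode` cell semantics, so the field of view is
preserved). The result is a fractional occupancy per PET voxel. Linearity
of trilinear interpolation guarantees partition of unity: per voxel, the
region fractions sum to the downsampled whole-brain indicator, so
per-region activities sum to the whole-VOI activity by construction.
Fractions below 1e-3 are zeroed (sparsity cutoff) — this is far below any
quantity of interest and keeps the fraction arrays sparse.

The brain mask on the PET grid is `total fraction > 0.5`. A bilateral
region can be split into hemispheres at its bounding-box midplane on the
MRI grid, before resampling; by the radiological file convention the
lower-coordinate half along the left-right axis is "right".

## 5. VOI segmentation

Two procedures cover the two tracer archetypes.

**Metabolic tracers** (uniform brain uptake): the caudal third of the
volume is dropped (`drop_caudal_third`) to remove torso and harderian
confounds, then an adaptive threshold is searched by bisection, seeded at
the Otsu threshold, until the largest connected component above threshold
matches the atlas brain-mask voxel count within ±20%. The candidate is
contour-matched against the binarized atlas mask over a rotation grid, and
the VOI is the candidate restricted to the best-placed atlas mask (dilated
by one voxel).

**Target-selective tracers** (dim brain, focal lesion, bright extra-brain
structures): after thresholding, a morphological reduction is applied —
3-D hole filling plus per-axial-slice filling (a truncated head shell is
open in 3-D but annular per slice), a 3×3×3 opening, a distance-transform
watershed to split touching components, and retention of components
overlapping the central axial band. The surviving candidate is eroded to
the atlas size and up to five seed points are placed at distance-transform
maxima for the contour match.

**Contour matching** uses the boundary F1 (BF) score: precision/recall of
boundary voxels within a tolerance (default 1 voxel), combined as F1. The
atlas mask is rotated through a per-axis grid of −20° … 20° in 2° steps
(rotations about the volume centre), embedded into the candidate's grid
(center pad/crop), and shifted so its centroid lands on the candidate
centroid. The default `sequential` mode optimises one axis at a time (3 ×
21 evaluations); `exhaustive` scans the 21³ grid. Ties resolve toward the
smallest total |angle|, then lexicographically, so the search is
deterministic.

*Resolution limit:* a 2° step moves a boundary point at lever arm `r` by
`r·sin(2°) ≈ 0.035·r` voxels. With a 1-voxel tolerance, rotations are only
resolvable for elongated (non-degenerate) masks whose lever arm exceeds
~30 voxels; for compact or near-axisymmetric masks the BF score saturates
and the search correctly returns the identity. Angle-recovery guarantees
are therefore stated for elongated masks only.

## 6. Template construction

The template reference is the control image whose VOI is *least rotated*:
each VOI's inertia tensor is eigendecomposed, axes are assigned
(longest→z, middle→x, shortest→y, matching the prone scanner layout), and
the member with the smallest sum of absolute axis angles wins. The
reference VOI centroid is moved to the grid centre by a pure integer shift
(no interpolation; a warning is raised if content is cropped).

Every other member is registered to the centred reference (rigid, then
optionally B-spline deformable) and the template is the voxel-wise mean.
The template VOI is then re-segmented *on the template itself* — for
metabolic tracers with the metabolic procedure, for target-selective
tracers by an inverted-intensity procedure: crop to the content bounding
box, exclude voxels above half maximum (bright extra-brain structures),
contrast-stretch and invert, take the skeletonized Otsu boundary of the
gradient magnitude, and grow the VOI from the centre by binary propagation
constrained to (a) non-boundary voxels and (b) voxels above the lower
threshold of a two-class Otsu split of the non-excluded intensities. The
second constraint stops leakage across the weak brain/background edge,
where the gradient skeleton alone is unreliable.

An optional *second template* can be built for a designated experimental
group whose anatomy differs systematically (e.g. lesioned animals); members
of that group are aligned rigid-only to the first template through the
second one, which avoids deformable registration absorbing the group
effect.

## 7. Registration

All registration is via SimpleITK with physical coordinates in millimetres
(converted from micrometre spacing). Transforms map *fixed-image points
into the moving image* (the resampling convention). Chains of transforms
are composed and applied in a **single** resampling pass, so repeated
alignment never compounds interpolation blur. A global one-thread setting
makes optimisation deterministic.

* **Rigid** (Euler 3-D) and **affine**: regular-step gradient descent with
  `min_step = 1e-5` (mapped to SimpleITK's `gradientMagnitudeTolerance`),
  multi-resolution shrink factors 4/2/1, moments initialisation. Rigid
  uses mean squares by default; affine uses correlation.
* **Deformable**: B-spline FFD optimised by L-BFGS-B, 50 iterations at
  tolerance 1e-5, with 10% random metric sampling at a fixed seed (1234).
  The optimum on brain-sized volumes is reached within tens of iterations;
  the looser budget changes runtime, not the converged similarity.
* **Within-subject alignment**: each subject's non-control states are
  rigidly registered to the control using a tracer-specific auxiliary
  volume — metabolic: the thresholded foreground of the caudally truncated
  image (brain plus connected hot structures); target-selective: the
  intensity-inverted brain VOI plus the halved-intensity head.
* **MRI co-registration**: two affine steps — gradient-magnitude images
  under correlation (500 iterations), then the template VOI volume onto the
  resized MRI brain under mutual information (2000 iterations).
* **Similarity reports** (Pearson, Spearman, joint entropy and mutual
  information from a 64-bin joint histogram, in bits) are logged before and
  after every registration and exported to `similarity.csv`; 64 bins is a
  standard compromise between bias and variance at these volume sizes.

An FFT-based rigid oracle (`reference_rigid_register`, exhaustive rotation
grid + phase-correlation shift) is provided for testing; it shares no code
with the production path.

## 8. Quantification

For each animal, interval and region, on the *original* preprocessed
dynamic frames resampled once into the atlas frame:

* `region activity (Bq) = Σ_v fraction_r(v) · concentration(v) · voxel_volume`,
  with interpolation undershoot clamped at zero;
* **A_N** = region activity / injected activity (dimensionless);
* **SUV** = region concentration / (injected activity / body weight), in
  g/mL; e.g. 5 kBq/mL at 25 MBq injected into a 250 g animal gives exactly
  0.05 g/mL;
* **UR** = region activity / reference activity, where the reference is the
  whole VOI (default) or a named region (e.g. cerebellum). UR is invariant
  under global intensity rescaling by construction; an SUVR-like
  concentration ratio is available via `ur_on_concentration`.

Σ over regions of A_N equals whole-VOI A_N to ~1e-6 relative (exact up to
floating-point summation order, by partition of unity).

## 9. Group statistics

Preclinical cohorts are small, so the default inference is nonparametric
(`n < 30` per group): Wilcoxon signed-rank (2 paired states), Friedman with
signed-rank post-hocs (≥3 paired states), Wilcoxon rank-sum / Kruskal-Wallis
for unpaired designs. Normality diagnostics (Shapiro-Wilk,
Anderson-Darling) and repeated-measures ANOVA are reported alongside for
reference, never as the primary test.

Exact null distributions are used at small n — Friedman by dynamic
programming over rank-sum vectors (n ≤ 8), signed-rank by full 2^n
enumeration (n ≤ 15), rank-sum by the U-statistic recursion (combined
n ≤ 20, no ties) — switching to tie-corrected normal/χ² approximations
beyond. Optional Holm correction across regions. QQ and box plots are
emitted per region/parameter in PNG and SVG.

## 10. Digital phantom

The test fixture is a fully synthetic rat-head phantom: a 160×128×128 MRI
grid at 400 μm with an ellipsoidal brain (semi-axes 44/26/34 voxels)
partitioned into six anatomically named sectors, and a 64×64×80 PET grid at
800 μm (scale factor exactly 1/2). Tracer patterns: metabolic (uniform
brain + hot glands) and target-selective (dim brain + focal lesion + bright
head shell). Per acquisition, a known rigid perturbation is applied and
frames receive Gaussian noise with variance proportional to intensity
(a Poisson surrogate), from a per-animal `SeedSequence` stream — fixed
seeds reproduce identical bytes. Ground truth (transform, region means)
accompanies every image, so registration, segmentation and quantification
can be validated in closed loop. The phantom makes no attempt at PET
physics (no scatter, randoms or PSF) and its anatomy is deliberately
schematic; quantitative claims validated on it are claims about the
*numerics*, not about scanner realism.

## 11. Reproducibility

`nudpa run --config cfg.yaml` writes `manifest.json` (package version,
seed, SHA-256 of the resolved configuration, scale factor, template
reference). Two runs with the same configuration and seed produce
byte-identical quantification CSVs. All randomness flows from the single
configured seed; SimpleITK metric sampling uses a fixed internal seed and
one thread.
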