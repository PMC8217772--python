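"""Spatial alignment: rigid, affine and deformable registration plus
transform reuse and similarity reporting.

The alignment strategy is hierarchical.  Within one animal, disease-state
images are rigidly registered onto the control state; auxiliary structures
connected to the brain (the Harderian glands for a metabolic tracer, the
halved-intensity head for a target-selective one) stabilise the rigid fit.
Across animals, control images are deformably registered (cubic-B-spline
parametrization, correlation-coefficient metric) onto the PET template, and
each animal's remaining states reuse its control transform chain verbatim.
Finally the template is co-registered to the MRI T2* image in two affine
steps, which — because the atlas labels live in MRI space — places every
image in atlas space by transform composition.

All registrations run on min-max normalized intensity copies; resampling is
always applied to the original data.  Every transform is recorded so it can
be reapplied to further images of the same animal.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import SimpleITK as sitk
from scipy import ndimage, stats

# single-threaded metric evaluation: summation order, and hence optimizer
# trajectories, stay identical regardless of the host CPU count
sitk.ProcessObject_SetGlobalDefaultNumberOfThreads(1)

from .io_preprocess import BinaryMask, DynamicImage, VolumeImage
from .segmentation import adaptive_volume_threshold, drop_caudal_third, otsu_thresholds

logger = logging.getLogger("nudpa.registration")

#: optimizer settings mirrored from the original pipeline
RIGID_MAX_ITER = 2000
RIGID_TOLERANCE = 1e-21
#: LBFGSB budget for the B-spline stage; looser settings give the same
#: post-alignment correlation at a fraction of the cost on brain-sized PET
#: volumes (the optimum is reached within tens of iterations)
DEFORMABLE_MAX_ITER = 50
DEFORMABLE_TOLERANCE = 1e-5
COREG_STEP1_MAX_ITER = 500
COREG_STEP2_MAX_ITER = 2000
COREG_TOLERANCE = 1e-15

#: joint-histogram binning of the similarity report
JOINT_HIST_BINS = 64


class RegistrationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# SimpleITK bridging
# ---------------------------------------------------------------------------


def to_sitk(vol: VolumeImage | BinaryMask) -> sitk.Image:
    """Internal (z, y, x) array with um spacing -> SimpleITK image (mm)."""
    arr = vol.voxels.astype(np.float64)
    img = sitk.GetImageFromArray(arr)
    sz, sy, sx = vol.spacing
    img.SetSpacing((sx / 1000.0, sy / 1000.0, sz / 1000.0))
    return img


def from_sitk(img: sitk.Image) -> VolumeImage:
    arr = sitk.GetArrayFromImage(img)
    sx, sy, sz = img.GetSpacing()
    return VolumeImage(arr, (sz * 1000.0, sy * 1000.0, sx * 1000.0))


def _normalized(vol: VolumeImage) -> VolumeImage:
    v = vol.voxels
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return VolumeImage(np.zeros_like(v), vol.spacing)
    return VolumeImage((v - lo) / (hi - lo), vol.spacing)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------


@dataclass
class Transform:
    """A parametric spatial mapping between two image frames.

    ``sitk_transform`` maps points of the fixed frame into the moving frame
    (the resampling convention); ``fixed_grid`` records the fixed frame's
    (shape, spacing) so chains know their output grid.
    """

    kind: str  # rigid | affine | deformable
    sitk_transform: sitk.Transform
    fixed_frame: str = "fixed"
    moving_frame: str = "moving"
    fixed_grid: tuple[tuple[int, int, int], tuple[float, float, float]] | None = None
    final_metric: float | None = None

    def parameters(self) -> dict:
        t = self.sitk_transform
        if self.kind == "rigid":
            e = sitk.Euler3DTransform(t)
            return {
                "rotation_deg": [float(np.degrees(a)) for a in e.GetParameters()[:3]],
                "translation_um": [p * 1000.0 for p in e.GetParameters()[3:6]],
                "center_mm": list(e.GetCenter()),
            }
        if self.kind == "affine":
            a = sitk.AffineTransform(t)
            return {
                "matrix": list(a.GetMatrix()),
                "translation_um": [p * 1000.0 for p in a.GetTranslation()],
                "center_mm": list(a.GetCenter()),
            }
        return {"note": "deformable; displacement field stored separately"}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "fixed_frame": self.fixed_frame,
            "moving_frame": self.moving_frame,
            "parameters": self.parameters(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class TransformChain:
    """Ordered transforms; applying the chain resamples an image through all
    steps in one interpolation pass."""

    steps: list[Transform] = field(default_factory=list)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if prev.fixed_frame != nxt.moving_frame:
                raise ValueError(
                    f"incompatible chain: {prev.fixed_frame!r} -> {nxt.moving_frame!r}"
                )

    def composite(self) -> sitk.CompositeTransform:
        comp = sitk.CompositeTransform(3)
        # the last-added transform is applied to the point first, so add in
        # image-application order: the final step's transform maps the output
        # grid back through every stage
        for step in self.steps:
            comp.AddTransform(step.sitk_transform)
        return comp

    @property
    def output_grid(self):
        if not self.steps:
            return None
        return self.steps[-1].fixed_grid


def identity_chain(frame: str = "fixed") -> TransformChain:
    return TransformChain([])


def apply_transform(
    img: DynamicImage | VolumeImage,
    chain: TransformChain,
    reference: VolumeImage | None = None,
) -> DynamicImage | VolumeImage:
    """Resample an image through a transform chain in a single trilinear pass.

    Every frame of a dynamic image receives the identical spatial mapping.
    ``reference`` overrides the output grid (defaults to the chain's final
    fixed grid, or the input grid for an empty chain).
    """
    is_dynamic = isinstance(img, DynamicImage)
    frames = img.voxels if is_dynamic else img.voxels[np.newaxis]
    spacing = img.spacing

    if not chain.steps and reference is None:
        out = frames.copy()
        ref_spacing = spacing
    else:
        if reference is not None:
            ref_img = to_sitk(reference)
            ref_spacing = reference.spacing
        else:
            shape, ref_spacing = chain.output_grid
            ref_img = sitk.Image(
                (int(shape[2]), int(shape[1]), int(shape[0])), sitk.sitkFloat64
            )
            sz, sy, sx = ref_spacing
            ref_img.SetSpacing((sx / 1000.0, sy / 1000.0, sz / 1000.0))
        comp = chain.composite()
        out = np.empty((frames.shape[0],) + tuple(ref_img.GetSize())[::-1])
        for i, frame in enumerate(frames):
            mov = to_sitk(VolumeImage(frame, spacing))
            res = sitk.Resample(mov, ref_img, comp, sitk.sitkLinear, 0.0)
            out[i] = sitk.GetArrayFromImage(res)
    if is_dynamic:
        return DynamicImage(out, ref_spacing, list(img.frame_schedule), dict(img.meta))
    return VolumeImage(out[0], ref_spacing)


# ---------------------------------------------------------------------------
# Registration backends
# ---------------------------------------------------------------------------


def _fixed_grid(vol: VolumeImage):
    return (tuple(int(s) for s in vol.voxels.shape), vol.spacing)


def _run_registration(
    reg: sitk.ImageRegistrationMethod,
    fixed: sitk.Image,
    moving: sitk.Image,
    initial: sitk.Transform,
) -> tuple[sitk.Transform, float]:
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetInitialTransform(initial, inPlace=True)
    try:
        result = reg.Execute(fixed, moving)
    except RuntimeError as exc:
        raise RegistrationError(str(exc)) from exc
    metric = reg.GetMetricValue()
    if not np.isfinite(metric):
        raise RegistrationError(f"registration diverged (metric {metric})")
    return result, float(metric)


def rigid_register(
    moving: VolumeImage,
    fixed: VolumeImage,
    *,
    metric: str = "mean_squares",
    max_iter: int = RIGID_MAX_ITER,
    tolerance: float = RIGID_TOLERANCE,
    min_step: float = 1e-5,
    fixed_frame: str = "fixed",
    moving_frame: str = "moving",
) -> Transform:
    """Rotation + translation registration of ``moving`` onto ``fixed``.

    Intensities are min-max normalized for the optimization only.  The
    default intensity metric is mean squares (mono-modal pairs); mutual
    information is available for cross-modality use.  ``tolerance`` bounds
    the gradient magnitude at convergence; ``min_step`` is the step-halving
    optimizer's resolution (well below the 0.5-voxel accuracy goal).
    """
    f, m = to_sitk(_normalized(fixed)), to_sitk(_normalized(moving))
    reg = sitk.ImageRegistrationMethod()
    if metric == "mean_squares":
        reg.SetMetricAsMeanSquares()
    elif metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(0.5, seed=1234)
    else:
        raise ValueError(f"unknown metric: {metric}")
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=min_step,
        numberOfIterations=max_iter,
        gradientMagnitudeTolerance=max(tolerance, 0.0),
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    result, metric_val = _run_registration(reg, f, m, sitk.Euler3DTransform(initial))
    logger.info("rigid %s->%s metric %.6g", moving_frame, fixed_frame, metric_val)
    return Transform(
        "rigid", result, fixed_frame, moving_frame, _fixed_grid(fixed), metric_val
    )


def affine_register(
    moving: VolumeImage,
    fixed: VolumeImage,
    metric: str = "correlation",
    *,
    max_iter: int = COREG_STEP2_MAX_ITER,
    tolerance: float = COREG_TOLERANCE,
    min_step: float = 1e-5,
    fixed_frame: str = "fixed",
    moving_frame: str = "moving",
) -> Transform:
    """Full affine registration (rotation, translation, scale, shear)."""
    f, m = to_sitk(_normalized(fixed)), to_sitk(_normalized(moving))
    reg = sitk.ImageRegistrationMethod()
    if metric == "correlation":
        reg.SetMetricAsCorrelation()
    elif metric == "mutual_information":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=32)
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(0.5, seed=1234)
    else:
        raise ValueError(f"unknown metric: {metric}")
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=min_step,
        numberOfIterations=max_iter,
        gradientMagnitudeTolerance=max(tolerance, 0.0),
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    initial = sitk.CenteredTransformInitializer(
        f, m, sitk.AffineTransform(3), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    result, metric_val = _run_registration(reg, f, m, sitk.AffineTransform(initial))
    logger.info("affine %s->%s metric %.6g", moving_frame, fixed_frame, metric_val)
    return Transform(
        "affine", result, fixed_frame, moving_frame, _fixed_grid(fixed), metric_val
    )


def deformable_register(
    moving: VolumeImage,
    fixed: VolumeImage,
    *,
    mesh_size: tuple[int, int, int] = (5, 5, 5),
    max_iter: int = DEFORMABLE_MAX_ITER,
    tolerance: float = DEFORMABLE_TOLERANCE,
    sampling_fraction: float = 0.1,
    fixed_frame: str = "fixed",
    moving_frame: str = "moving",
) -> Transform:
    """Non-rigid registration: cubic-B-spline transform, correlation metric.

    A rigid pre-alignment initializes the B-spline stage so the deformation
    only has to account for shape differences.  The correlation metric is
    evaluated on a deterministic (fixed-seed) random subset of the voxels;
    ``sampling_fraction = 1`` uses every voxel at roughly 5x the cost for no
    measurable alignment gain on brain-sized volumes.
    """
    pre = rigid_register(
        moving, fixed, fixed_frame=fixed_frame, moving_frame=moving_frame
    )
    f = to_sitk(_normalized(fixed))
    m_pre = to_sitk(
        _normalized(apply_transform(moving, TransformChain([pre])))
    )
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    if sampling_fraction < 1.0:
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(sampling_fraction, seed=1234)
    reg.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=tolerance,
        numberOfIterations=max_iter,
        maximumNumberOfCorrections=5,
    )
    tx = sitk.BSplineTransformInitializer(f, [int(s) for s in mesh_size], order=3)
    result, metric_val = _run_registration(reg, f, m_pre, tx)
    logger.info("deformable %s->%s metric %.6g", moving_frame, fixed_frame, metric_val)
    comp = sitk.CompositeTransform(3)
    comp.AddTransform(pre.sitk_transform)
    comp.AddTransform(result)
    return Transform(
        "deformable", comp, fixed_frame, moving_frame, _fixed_grid(fixed), metric_val
    )


# ---------------------------------------------------------------------------
# Reference (oracle) rigid registration — slow but library-free
# ---------------------------------------------------------------------------


def reference_rigid_register(
    moving: VolumeImage,
    fixed: VolumeImage,
    angle_range_deg: float = 12.0,
    angle_step_deg: float = 1.0,
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Exhaustive rigid search used as an independent oracle in tests.

    Scans z/y/x rotations sequentially on a coarse grid; at each rotation the
    best integer translation is found by FFT cross-correlation.  Returns
    (angles_deg about (z, y, x), translation in voxels (z, y, x)) mapping the
    moving image onto the fixed one.
    """
    from numpy.fft import fftn, ifftn

    fx = _normalized(fixed).voxels
    mv = _normalized(moving).voxels

    def best_shift_and_score(m: np.ndarray) -> tuple[np.ndarray, float]:
        corr = np.real(ifftn(fftn(fx) * np.conj(fftn(m))))
        idx = np.unravel_index(np.argmax(corr), corr.shape)
        shift = np.array(
            [i if i <= n // 2 else i - n for i, n in zip(idx, corr.shape)]
        )
        return shift, float(corr[idx])

    angles = [0.0, 0.0, 0.0]
    planes = [(1, 2), (0, 2), (0, 1)]
    grid = np.arange(-angle_range_deg, angle_range_deg + 1e-9, angle_step_deg)
    best_shift = np.zeros(3)
    for axis in range(3):
        best_score = -np.inf
        for a in grid:
            trial = list(angles)
            trial[axis] = float(a)
            m = mv
            for ax, ang in zip(planes, trial):
                if ang:
                    m = ndimage.rotate(m, ang, axes=ax, reshape=False, order=1)
            shift, score = best_shift_and_score(m)
            if score > best_score:
                best_score, angles[axis], best_shift = score, float(a), shift
    return tuple(angles), tuple(float(s) for s in best_shift)


# ---------------------------------------------------------------------------
# Auxiliary structures for rigid alignment
# ---------------------------------------------------------------------------


def build_aux_metabolic(img: VolumeImage, atlas_mask: BinaryMask) -> VolumeImage:
    """Brain plus connected high-uptake structures (Harderian glands).

    The metabolic reduction is truncated right after the adaptive volume
    threshold: the caudally truncated image is masked to the full thresholded
    foreground, which keeps the brain together with any bright connected
    structures that stabilise rigid registration.
    """
    if not (img.voxels != 0).any():
        raise RegistrationError("all-zero image")
    work = drop_caudal_third(img)
    _mask, thr = adaptive_volume_threshold(work, atlas_mask.count())
    fg = work.voxels > thr
    return VolumeImage(work.voxels * fg, img.spacing)


def _contrast_stretch_invert(values: np.ndarray) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.ones_like(values)
    return 1.0 - (values - lo) / (hi - lo)


def build_aux_target(img: VolumeImage, voi: BinaryMask) -> VolumeImage:
    """Intensity-inverted brain VOI plus the halved-intensity head.

    (a) the 1-voxel-dilated VOI is cut from the original image and its
    intensities contrast-stretched and inverted, highlighting the dim healthy
    brain tissue; (b) the filled binary head mask is cropped in x/y to the
    VOI bounding cuboid and in z to the rostral half, minus the inverted-VOI
    voxels; (c) the original image under the head mask is halved (the head is
    only a helping structure); (d) the two volumes are summed.
    """
    vox = img.voxels
    dil_voi = ndimage.binary_dilation(voi.voxels, structure=np.ones((3, 3, 3), bool))
    inv = np.zeros_like(vox)
    if dil_voi.any():
        inv[dil_voi] = _contrast_stretch_invert(vox[dil_voi])

    try:
        thr = otsu_thresholds(vox[vox > 0] if (vox > 0).any() else vox)[0]
    except Exception:
        thr = 0.0
    head = ndimage.binary_fill_holes(vox > thr)
    zs, ys, xs = np.nonzero(voi.voxels) if voi.voxels.any() else (np.array([0]),) * 3
    crop = np.zeros_like(head)
    nz = head.shape[0]
    crop[: nz // 2, ys.min() : ys.max() + 1, xs.min() : xs.max() + 1] = True
    head = head & crop & ~dil_voi
    if not head.any():
        warnings.warn("empty head mask; returning inverted VOI only", stacklevel=2)
        return VolumeImage(inv, img.spacing)
    return VolumeImage(inv + 0.5 * vox * head, img.spacing)


# ---------------------------------------------------------------------------
# Cohort-level alignment
# ---------------------------------------------------------------------------


@dataclass
class AlignedSubject:
    name: str
    states: list[str]
    images: list[DynamicImage]  # aligned, control first
    chains: list[TransformChain]  # per state, control chain is empty


def align_subject_states(
    series: dict[str, list[tuple[str, DynamicImage]]],
    aux_builder: Callable[[VolumeImage], VolumeImage],
) -> dict[str, AlignedSubject]:
    """Rigidly align each subject's disease states onto its control state.

    ``series`` maps subject name to (state, image) pairs with the control
    state first (the ordering produced by repeat-measurement detection).
    Registration runs on the auxiliary-structure volumes built from the
    summed images; the resulting rigid transform is applied to the full
    dynamic data.  Subjects without a control state pass through unchanged
    with a warning (they are aligned directly to the template later).
    """
    from .io_preprocess import sum_frames

    out: dict[str, AlignedSubject] = {}
    for name, entries in series.items():
        states = [s for s, _ in entries]
        images = [img for _, img in entries]
        chains: list[TransformChain] = [TransformChain([])]
        aligned = [images[0]]
        if len(entries) == 1:
            out[name] = AlignedSubject(name, states, aligned, chains)
            continue
        control_aux = aux_builder(sum_frames(images[0]))
        for state, img in entries[1:]:
            aux = aux_builder(sum_frames(img))
            t = rigid_register(
                aux,
                control_aux,
                fixed_frame=f"{name}:{states[0]}",
                moving_frame=f"{name}:{state}",
            )
            chain = TransformChain([t])
            aligned.append(apply_transform(img, chain))
            chains.append(chain)
        out[name] = AlignedSubject(name, states, aligned, chains)
    return out


def align_to_template(
    subjects: dict[str, AlignedSubject],
    template_image: VolumeImage,
    template_frame: str = "template",
) -> dict[str, AlignedSubject]:
    """Deformably register every subject's control image to the template and
    reuse the control chain for all other states of the same subject."""
    from .io_preprocess import sum_frames

    out: dict[str, AlignedSubject] = {}
    for name, subj in subjects.items():
        control_summed = sum_frames(subj.images[0])
        t = deformable_register(
            control_summed,
            template_image,
            fixed_frame=template_frame,
            moving_frame=f"{name}:{subj.states[0]}",
        )
        chain = TransformChain([t])
        aligned = [apply_transform(img, chain) for img in subj.images]
        chains = [
            TransformChain(list(c.steps) + [t]) if c.steps else chain
            for c in subj.chains
        ]
        out[name] = AlignedSubject(name, subj.states, aligned, chains)
    return out


def coregister_to_mri(
    template_image: VolumeImage,
    template_voi: BinaryMask,
    mri_t2_resized: VolumeImage,
    mri_brain_mask: BinaryMask,
) -> TransformChain:
    """Two-step affine co-registration of the PET template onto the MRI T2*.

    Step 1 pre-adjusts by registering the gradient-magnitude images (500
    iterations); step 2 registers the template VOI volume onto the resized
    MRI brain volume with a mutual-information metric (2000 iterations).
    Because the atlas labels are co-registered with the MRI, the returned
    chain maps template space into atlas space.
    """
    try:
        g_pet = gradient_magnitude(template_image)
        g_mri = gradient_magnitude(mri_t2_resized)
        t1 = affine_register(
            g_pet,
            g_mri,
            metric="correlation",
            max_iter=COREG_STEP1_MAX_ITER,
            tolerance=COREG_TOLERANCE,
            fixed_frame="mri",
            moving_frame="template",
        )
    except RegistrationError as exc:
        raise RegistrationError(f"co-registration step 1 (gradients): {exc}") from exc
    try:
        voi_vol = VolumeImage(
            template_image.voxels * template_voi.voxels, template_image.spacing
        )
        voi_aligned = apply_transform(voi_vol, TransformChain([t1]))
        mri_brain = VolumeImage(
            mri_t2_resized.voxels * mri_brain_mask.voxels, mri_t2_resized.spacing
        )
        t2 = affine_register(
            voi_aligned,
            mri_brain,
            metric="mutual_information",
            max_iter=COREG_STEP2_MAX_ITER,
            tolerance=COREG_TOLERANCE,
            fixed_frame="atlas",
            moving_frame="mri",
        )
    except RegistrationError as exc:
        raise RegistrationError(f"co-registration step 2 (VOI): {exc}") from exc
    return TransformChain([t1, t2])


def gradient_magnitude(vol: VolumeImage) -> VolumeImage:
    """Central-difference gradient magnitude (per-voxel units)."""
    grads = np.gradient(vol.voxels)
    return VolumeImage(np.sqrt(sum(g * g for g in grads)), vol.spacing)


# ---------------------------------------------------------------------------
# Similarity reporting
# ---------------------------------------------------------------------------


@dataclass
class SimilarityReport:
    pearson: float
    spearman: float
    joint_entropy: float  # bits
    mutual_information: float  # bits
    scope: str = "full-image"
    phase: str = "after"
    degenerate: bool = False

    def as_row(self) -> dict:
        return dict(self.__dict__)


def similarity_report(
    a: VolumeImage,
    b: VolumeImage,
    mask: BinaryMask | None = None,
    scope: str | None = None,
    phase: str = "after",
) -> SimilarityReport:
    """Correlation and information-theoretic agreement of two volumes.

    Pearson and Spearman correlations run over the (masked) voxel pairs; the
    joint histogram uses 64 equal-width bins per image over its own range,
    from which joint entropy and mutual information are computed in bits.
    Constant images are flagged degenerate (correlations undefined).
    """
    if a.voxels.shape != b.voxels.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        x, y = a.voxels[mask.voxels], b.voxels[mask.voxels]
        scope = scope or "voi"
    else:
        x, y = a.voxels.ravel(), b.voxels.ravel()
        scope = scope or "full-image"
    degenerate = bool(np.ptp(x) == 0 or np.ptp(y) == 0)
    if degenerate:
        pearson = spearman = float("nan")
    else:
        pearson = float(stats.pearsonr(x, y).statistic)
        spearman = float(stats.spearmanr(x, y).statistic)
    hist, _, _ = np.histogram2d(x, y, bins=JOINT_HIST_BINS)
    p = hist / hist.sum()
    nz = p > 0
    joint_entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    px, py = p.sum(axis=1), p.sum(axis=0)
    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
    mi = hx + hy - joint_entropy
    return SimilarityReport(pearson, spearman, joint_entropy, max(mi, 0.0),
                            scope, phase, degenerate)
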