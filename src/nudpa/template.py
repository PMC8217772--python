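"""PET template construction and template-VOI segmentation.

A study-specific PET template is the common registration target for the
cohort.  Among the control-group images, the one whose segmented brain VOI is
best aligned with the coordinate axes (smallest principal-axis angles) is
chosen as the reference; it is centred on its VOI centroid and every other
control is deformably registered onto it; the voxel-wise mean is the
template.  The template's own VOI is then segmented — with the metabolic
procedure for a uniformly accumulating tracer, or via intensity inversion and
a skeletonized-gradient boundary for a target-selective tracer whose template
shows only focal uptake.

An optional second template compensates severe uptake alterations between an
experimental group and the controls: it is built from the designated
experimental group with *rigid* member alignment only (strongly altered
uptake would mislead a deformable fit), then rigidly mapped onto the primary
template so that all images end in one space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .io_preprocess import BinaryMask, VolumeImage
from .registration import (
    AlignedSubject,
    RegistrationError,
    Transform,
    TransformChain,
    apply_transform,
    deformable_register,
    rigid_register,
)
from .segmentation import (
    SegmentationFailure,
    _largest_component,
    integer_shift,
    otsu_thresholds,
    segment_voi_metabolic,
)


@dataclass
class OrientationAngles:
    """Principal-axis orientation of a VOI mask.

    The brain is roughly ellipsoidal and the animal lies along the scanner
    axis, so the longest principal axis is assigned to z, the middle one to
    x and the shortest to y; each angle is measured between the assigned
    eigenvector and its coordinate axis, in [0, 90] degrees.
    """

    theta_z: float
    theta_x: float
    theta_y: float
    axis_lengths: tuple[float, float, float]  # long -> short, um
    centroid: tuple[float, float, float]  # voxel coordinates (z, y, x)

    @property
    def total(self) -> float:
        return self.theta_z + self.theta_x + self.theta_y


@dataclass
class Template:
    image: VolumeImage
    voi_mask: BinaryMask
    reference_id: str
    member_transforms: dict[str, TransformChain] = field(default_factory=dict)


def voi_orientation(mask: BinaryMask, isotropy_tol: float = 0.02) -> OrientationAngles:
    """Principal axes of a mask from its second-moment eigendecomposition."""
    vox = mask.voxels
    if not vox.any():
        raise ValueError("empty mask")
    coords = np.argwhere(vox).astype(np.float64)
    centroid_vox = coords.mean(axis=0)
    phys = (coords - centroid_vox) * np.array(mask.spacing)
    cov = phys.T @ phys / len(phys)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    evals, evecs = evals[::-1], evecs[:, ::-1]  # longest first
    if evals[0] <= 0:
        raise ValueError("degenerate mask (zero extent)")
    spreads = np.sqrt(evals)
    if (spreads[0] - spreads[2]) / spreads[0] < isotropy_tol:
        raise ValueError("isotropic mask: principal axes are not distinct")
    # uniform ellipsoid: second moment along a semi-axis a is a^2/5
    lengths = tuple(float(2 * np.sqrt(5 * ev)) for ev in evals)
    # array axes: 0 = z, 1 = y, 2 = x; long -> z, middle -> x, short -> y
    axis_unit = {"z": np.array([1.0, 0, 0]), "y": np.array([0, 1.0, 0]),
                 "x": np.array([0, 0, 1.0])}

    def angle(vec: np.ndarray, axis: str) -> float:
        c = abs(float(vec @ axis_unit[axis])) / float(np.linalg.norm(vec))
        return float(np.degrees(np.arccos(np.clip(c, -1, 1))))

    return OrientationAngles(
        theta_z=angle(evecs[:, 0], "z"),
        theta_x=angle(evecs[:, 1], "x"),
        theta_y=angle(evecs[:, 2], "y"),
        axis_lengths=lengths,
        centroid=tuple(float(c) for c in centroid_vox),
    )


def select_reference(masks: list[BinaryMask]) -> int:
    """Index of the VOI best aligned with the axes (smallest angle sum);
    ties break toward the smallest z angle, then the lowest index."""
    if not masks:
        raise ValueError("need at least one mask")
    keys = []
    for i, m in enumerate(masks):
        o = voi_orientation(m)
        keys.append((o.total, o.theta_z, i))
    return min(keys)[2]


def center_voi(img: VolumeImage, mask: BinaryMask) -> tuple[VolumeImage, BinaryMask]:
    """Translate image and mask by whole voxels so the VOI centroid lands on
    the grid centre.  No interpolation; content shifted off-grid is cropped
    (with a warning)."""
    if not mask.voxels.any():
        raise ValueError("empty mask")
    centroid = np.array(ndimage.center_of_mass(mask.voxels))
    center = (np.array(mask.voxels.shape) - 1) / 2.0
    shift = tuple(int(round(s)) for s in (center - centroid))
    n_before = int((img.voxels != 0).sum())
    out_img = integer_shift(img.voxels, shift)
    out_mask = integer_shift(mask.voxels, shift)
    if int((out_img != 0).sum()) < n_before:
        warnings.warn("centering shifted content off the grid; cropped", stacklevel=2)
    return VolumeImage(out_img, img.spacing), BinaryMask(out_mask, mask.spacing)


def build_template(
    controls: list[VolumeImage],
    masks: list[BinaryMask],
    reference: int,
    *,
    member_ids: list[str] | None = None,
    member_registration: str = "deformable",
    aux_images: list[VolumeImage] | None = None,
) -> Template:
    """Average the control group into a template after alignment to the
    centred reference image.

    Members are registered with the deformable (B-spline, correlation-metric)
    backend by default; ``member_registration='rigid'`` restricts alignment to
    rotation+translation (used for the second template, where altered uptake
    would bias a deformable fit), optionally driven by auxiliary-structure
    images registered in place of the plain members.
    """
    if not controls:
        raise ValueError("need at least one control image")
    if not (0 <= reference < len(controls)):
        raise ValueError("reference index out of range")
    ids = member_ids or [f"control_{i}" for i in range(len(controls))]
    ref_img, ref_mask = center_voi(controls[reference], masks[reference])
    ref_aux = None
    if aux_images is not None:
        ref_aux, _ = center_voi(aux_images[reference], masks[reference])
    stack = [ref_img.voxels]
    transforms: dict[str, TransformChain] = {ids[reference]: TransformChain([])}
    for i, img in enumerate(controls):
        if i == reference:
            continue
        try:
            if member_registration == "deformable":
                t = deformable_register(
                    img, ref_img, fixed_frame="template_ref", moving_frame=ids[i]
                )
            elif member_registration == "rigid":
                moving = aux_images[i] if aux_images is not None else img
                t = rigid_register(
                    moving, ref_aux if ref_aux is not None else ref_img,
                    fixed_frame="template_ref", moving_frame=ids[i],
                )
            else:
                raise ValueError(f"unknown member registration: {member_registration}")
        except RegistrationError as exc:
            raise RegistrationError(f"template member {ids[i]}: {exc}") from exc
        chain = TransformChain([t])
        stack.append(apply_transform(img, chain).voxels)
        transforms[ids[i]] = chain
    mean = np.mean(stack, axis=0)
    return Template(
        VolumeImage(mean, ref_img.spacing),
        ref_mask,
        ids[reference],
        transforms,
    )


def segment_template_voi(
    template: Template, atlas_mask: BinaryMask, tracer_mode: str,
    *, search_mode: str = "sequential",
) -> Template:
    """Segment the template's VOI and attach it.

    Metabolic templates reuse the metabolic single-image procedure; target-
    selective templates use the intensity-inverted procedure.
    """
    if tracer_mode == "metabolic":
        res = segment_voi_metabolic(template.image, atlas_mask, search_mode=search_mode)
        voi = res.voi_mask
    elif tracer_mode == "target_selective":
        voi = segment_template_voi_inverted(template.image)
    else:
        raise ValueError(f"unknown tracer mode: {tracer_mode}")
    return Template(template.image, voi, template.reference_id,
                    dict(template.member_transforms))


def _content_bbox(vox: np.ndarray) -> tuple[slice, slice, slice]:
    nz = np.nonzero(vox)
    return tuple(slice(int(c.min()), int(c.max()) + 1) for c in nz)


def segment_template_voi_inverted(template_img: VolumeImage) -> BinaryMask:
    """Segment the VOI of a target-selective template by intensity inversion.

    The focal target (e.g. a stroke lesion) dominates the template intensity
    while the healthy brain is dim, so: crop to the content bounding cuboid
    (valid because the reference was centred); exclude voxels brighter than
    half the maximum; contrast-stretch the remainder to [0, 1] and invert so
    healthy tissue appears bright; take the skeletonized Otsu-thresholded
    gradient magnitude of the inverted volume as a boundary surface; and grow
    a seed at the grid centre by 1-voxel dilations that never cross boundary
    or excluded voxels.  The converged grown mask is the VOI.
    """
    vox = template_img.voxels
    if not (vox != 0).any():
        raise SegmentationFailure("empty template image")
    bbox = _content_bbox(vox)
    crop = vox[bbox]
    vmax = float(crop.max())
    valid = crop <= vmax / 2.0
    if not valid.any() or np.ptp(crop[valid]) == 0:
        raise SegmentationFailure(
            "intensity exclusion leaves no usable dynamic range "
            "(all remaining values equal)"
        )
    lo, hi = float(crop[valid].min()), float(crop[valid].max())
    inv = np.zeros_like(crop)
    inv[valid] = 1.0 - (crop[valid] - lo) / (hi - lo)

    grads = np.gradient(inv)
    gm = np.sqrt(sum(g * g for g in grads))
    thr = otsu_thresholds(gm.ravel())[0]
    boundary = skeletonize(gm > thr)
    # the gradient between dim tissue and empty background is weak compared
    # with the target/shell edges, so the skeleton alone leaks there; growth
    # is additionally confined to voxels with signal.  The non-excluded
    # intensities hold up to three classes (background, dim tissue, residual
    # bright rims), so the LOWER of a two-threshold Otsu split marks the
    # background/tissue divide.
    support = crop > otsu_thresholds(crop[valid], n_thresholds=2)[0]
    allowed = valid & support & ~boundary

    seed = tuple((np.array(crop.shape) - 1) // 2)
    if not allowed[seed]:
        # relocate to the nearest allowed voxel
        dist = ndimage.distance_transform_edt(~allowed)  # 0 at allowed voxels
        cand = np.argwhere(allowed)
        if cand.size == 0:
            raise SegmentationFailure("no voxel available for seed growth")
        d = np.linalg.norm(cand - np.array(seed), axis=1)
        seed = tuple(int(c) for c in cand[int(np.argmin(d))])
        del dist
    grown = np.zeros_like(allowed)
    grown[seed] = True
    struct = ndimage.generate_binary_structure(3, 1)
    grown = ndimage.binary_propagation(grown, structure=struct, mask=allowed)
    grown = _largest_component(grown)

    full = np.zeros(vox.shape, dtype=bool)
    full[bbox] = grown
    return BinaryMask(full, template_img.spacing)


def second_template_workflow(
    subjects: dict[str, AlignedSubject],
    primary: Template,
    atlas_mask: BinaryMask,
    aux_builder,
    *,
    enabled: bool = True,
    search_mode: str = "sequential",
) -> tuple[dict[str, AlignedSubject], Template | None]:
    """Align an experimental group through a second, rigidly built template.

    When disabled this is a plain deformable alignment onto the primary
    template.  When enabled, the designated group's control images are
    segmented with the metabolic procedure, a reference is selected by VOI
    orientation, a second template is built with rigid member alignment on
    auxiliary-structure volumes (deformable alignment is deliberately never
    used here: strongly altered uptake would corrupt it), and the second
    template is rigidly registered onto the primary template; every member's
    chain is extended accordingly.
    """
    from .io_preprocess import sum_frames
    from .registration import align_to_template

    if not enabled:
        return align_to_template(subjects, primary.image), None
    if len(subjects) < 2:
        raise ValueError("second-template group needs at least 2 subjects")

    names = list(subjects)
    summed = [sum_frames(subjects[n].images[0]) for n in names]
    segs = [segment_voi_metabolic(s, atlas_mask, search_mode=search_mode)
            for s in summed]
    masks = [s.voi_mask for s in segs]
    ref = select_reference(masks)
    aux = [aux_builder(s) for s in summed]
    second = build_template(
        summed, masks, ref,
        member_ids=names, member_registration="rigid", aux_images=aux,
    )
    bridge = rigid_register(
        second.image, primary.image,
        fixed_frame="template", moving_frame="template2",
    )
    out: dict[str, AlignedSubject] = {}
    for name in names:
        subj = subjects[name]
        to_second = second.member_transforms[name]
        # images are already in within-subject (control) space: apply only the
        # new steps, but record the full provenance chain per state
        new_steps = list(to_second.steps) + [bridge]
        apply_chain = TransformChain(_relabel(new_steps))
        aligned = [apply_transform(img, apply_chain) for img in subj.images]
        chains = [
            TransformChain(_relabel(list(c.steps) + new_steps))
            for c in subj.chains
        ]
        out[name] = AlignedSubject(name, subj.states, aligned, chains)
    return out, second


def _relabel(steps: list[Transform]) -> list[Transform]:
    """Make frame labels of concatenated steps chain-compatible."""
    out = []
    prev_fixed = None
    for s in steps:
        s2 = Transform(s.kind, s.sitk_transform, s.fixed_frame,
                       prev_fixed if prev_fixed is not None else s.moving_frame,
                       s.fixed_grid, s.final_metric)
        out.append(s2)
        prev_fixed = s2.fixed_frame
    return out
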