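"""Brain-VOI segmentation in summed PET images.

The volume of interest (the brain) is located in a summed PET image by
matching the contour of a thresholded candidate object against the binarized,
resized MRI atlas under a rotation search.  Two procedures exist:

* **metabolic** tracers (e.g. FDG) fill the whole brain roughly uniformly, so
  an adaptive intensity threshold already isolates a brain-sized connected
  object and a single contour match suffices;
* **target-selective** tracers (e.g. a p-selectin ligand) show only focal
  uptake inside a dim brain, so after thresholding the candidate must be
  reduced morphologically and interior voxels serve as candidate anchor
  points (seeds) for the contour match.

The match quality measure is the boundary-F1 (BF) score: the harmonic mean of
boundary precision and recall within a voxel distance tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.segmentation import watershed

from .io_preprocess import BinaryMask, DegenerateInputError, VolumeImage


class SegmentationFailure(RuntimeError):
    """No candidate object compatible with the atlas could be found."""


#: rotation grid of the contour-matching search, degrees
ROTATION_RANGE_DEG = (-20.0, 20.0)
ROTATION_STEP_DEG = 2.0

#: adaptive threshold loop: accept when the largest component is within
#: +-20% of the atlas voxel count; give up past +-50%
VOLUME_TOLERANCE = 0.20
VOLUME_FAIL_TOLERANCE = 0.50
MAX_THRESHOLD_ITER = 50


@dataclass
class SegmentationResult:
    voi_mask: BinaryMask
    best_rotation: tuple[float, float, float]  # degrees about (z, y, x)
    match_score: float
    threshold_used: float


# ---------------------------------------------------------------------------
# Stage operations
# ---------------------------------------------------------------------------


def drop_caudal_third(img: VolumeImage) -> VolumeImage:
    """Zero the last third of axial slices (the caudal end).

    The animal is centred manually in the scanner with the brain in the
    rostral part of the field of view; the caudal third contains neck and
    torso and is discarded before thresholding.
    """
    nz = img.voxels.shape[0]
    if nz < 3:
        raise DegenerateInputError("axial extent must be >= 3 slices")
    n_drop = nz // 3
    out = img.voxels.copy()
    out[nz - n_drop :] = 0.0
    return VolumeImage(out, img.spacing)


def otsu_thresholds(values: np.ndarray, n_thresholds: int = 1) -> list[float]:
    """Otsu threshold(s) maximizing between-class variance (256-bin histogram)."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("Otsu thresholding requires >=2 distinct values")
    if n_thresholds == 1:
        return [float(threshold_otsu(values, nbins=256))]
    return [float(t) for t in threshold_multiotsu(values, classes=n_thresholds + 1, nbins=256)]


def _largest_component(fg: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(fg)
    if n == 0:
        return np.zeros_like(fg, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=range(1, n + 1))
    return labeled == (int(np.argmax(sizes)) + 1)


def adaptive_volume_threshold(
    img: VolumeImage, target_voxel_count: int
) -> tuple[BinaryMask, float]:
    """Adapt the intensity threshold until the largest connected object is
    approximately the size of the resized MRI atlas.

    Starting from the Otsu threshold, the threshold is adjusted by bisection
    on the intensity range until the largest connected foreground component's
    voxel count is within +-20% of ``target_voxel_count`` (at most 50
    iterations).  Raising the threshold shrinks the object and vice versa.
    """
    if target_voxel_count <= 0:
        raise ValueError("target voxel count must be positive")
    vox = img.voxels
    try:
        t = otsu_thresholds(vox[vox > 0] if (vox > 0).any() else vox)[0]
    except DegenerateInputError as exc:
        raise SegmentationFailure(str(exc)) from exc
    lo, hi = float(vox.min()), float(vox.max())
    best_mask, best_thr, best_err = None, t, np.inf
    for _ in range(MAX_THRESHOLD_ITER):
        comp = _largest_component(vox > t)
        count = int(comp.sum())
        err = abs(count - target_voxel_count) / target_voxel_count
        if err < best_err:
            best_mask, best_thr, best_err = comp, t, err
        if err <= VOLUME_TOLERANCE:
            break
        if count > target_voxel_count:
            lo = t  # too big: raise threshold
        else:
            hi = t
        t = 0.5 * (lo + hi)
    if best_mask is None or best_err > VOLUME_FAIL_TOLERANCE:
        raise SegmentationFailure(
            f"no threshold yields an object within +-50% of {target_voxel_count} voxels "
            f"(best relative error {best_err:.2f})"
        )
    return BinaryMask(best_mask, img.spacing), float(best_thr)


# ---------------------------------------------------------------------------
# Boundary-F1 contour matching
# ---------------------------------------------------------------------------

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)


def bf_score(maskA: BinaryMask, maskB: BinaryMask, tol_voxels: float = 1.0) -> float:
    """Boundary-F1 score between two masks.

    Precision is the fraction of A's boundary voxels lying within
    ``tol_voxels`` (Euclidean, in voxels) of B's boundary; recall is the
    symmetric quantity; the score is their harmonic mean.  Two empty
    boundaries score 1; one empty boundary against a non-empty one scores 0.
    """
    a, b = maskA.voxels, maskB.voxels
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ba, bb = _boundary(a), _boundary(b)
    na, nb = int(ba.sum()), int(bb.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    dist_to_b = ndimage.distance_transform_edt(~bb)
    dist_to_a = ndimage.distance_transform_edt(~ba)
    precision = float((dist_to_b[ba] <= tol_voxels).mean())
    recall = float((dist_to_a[bb] <= tol_voxels).mean())
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# Rotation search
# ---------------------------------------------------------------------------

#: (axis name, plane of rotation as array-axis pair)
_ROTATION_PLANES = {"z": (1, 2), "y": (0, 2), "x": (0, 1)}


def rotate_mask(mask: np.ndarray, angles_deg: tuple[float, float, float]) -> np.ndarray:
    """Rotate a boolean volume about its centre, per axis (z, y, x order),
    nearest-neighbour resampling."""
    out = mask.astype(np.uint8)
    for axis_name, angle in zip(("z", "y", "x"), angles_deg):
        if angle == 0:
            continue
        out = ndimage.rotate(
            out,
            angle,
            axes=_ROTATION_PLANES[axis_name],
            reshape=False,
            order=0,
            mode="constant",
            cval=0,
        )
    return out.astype(bool)


def integer_shift(arr: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    """Shift a volume by whole voxels; content leaving the grid is cropped."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for n, s in zip(arr.shape, shift):
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _centroid(mask: np.ndarray) -> np.ndarray:
    return np.array(ndimage.center_of_mass(mask))


def _angle_grid() -> np.ndarray:
    lo, hi = ROTATION_RANGE_DEG
    grid = np.arange(lo, hi + ROTATION_STEP_DEG / 2, ROTATION_STEP_DEG)
    # evaluate small |angle| first so ties resolve toward zero rotation
    return np.array(sorted(grid, key=lambda a: (abs(a), a)))


def _fit_to_shape(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center-crop/pad a boolean array to ``shape`` (per-axis, independently)."""
    if arr.shape == tuple(shape):
        return arr
    out = np.zeros(shape, dtype=arr.dtype)
    src, dst = [], []
    for n_in, n_out in zip(arr.shape, shape):
        d = n_in - n_out
        if d >= 0:
            lo = d // 2
            src.append(slice(lo, lo + n_out))
            dst.append(slice(0, n_out))
        else:
            lo = (-d) // 2
            src.append(slice(0, n_in))
            dst.append(slice(lo, lo + n_in))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _place_atlas(
    atlas: np.ndarray,
    angles: tuple[float, float, float],
    anchor: np.ndarray,
    shape: tuple[int, ...] | None = None,
) -> tuple[np.ndarray, tuple[int, int, int]]:
    rotated = rotate_mask(atlas, angles)
    if shape is not None:
        rotated = _fit_to_shape(rotated, shape)
    if not rotated.any():
        return rotated, (0, 0, 0)
    offset = tuple(int(round(s)) for s in (anchor - _centroid(rotated)))
    return integer_shift(rotated, offset), offset


def rotation_search(
    candidate: BinaryMask,
    atlas_mask: BinaryMask,
    *,
    anchor: np.ndarray | None = None,
    mode: str = "sequential",
    tol_voxels: float = 1.0,
) -> tuple[tuple[float, float, float], tuple[int, int, int], float]:
    """Find the atlas rotation (and centroid offset) best matching a candidate.

    The binarized atlas is rotated through a 2-degree grid over -20..20
    degrees per axis about the volume centre, translated so its centroid
    lands on ``anchor`` (the candidate centroid by default), and scored with
    :func:`bf_score` against the candidate.  Ties are broken toward the
    smallest total absolute angle, then lexicographically by (z, y, x) angle.

    ``mode='sequential'`` optimizes one axis at a time (3 x 21 evaluations);
    ``mode='exhaustive'`` scans the full 21^3 grid.
    """
    if not atlas_mask.voxels.any():
        raise ValueError("atlas mask is empty")
    if not candidate.voxels.any():
        raise ValueError("candidate mask is empty")
    if anchor is None:
        anchor = _centroid(candidate.voxels)
    atlas = atlas_mask.voxels
    spacing = candidate.spacing
    grid = _angle_grid()

    def score(angles: tuple[float, float, float]) -> tuple[float, tuple[int, int, int]]:
        placed, offset = _place_atlas(atlas, angles, anchor,
                                      shape=candidate.voxels.shape)
        return bf_score(candidate, BinaryMask(placed, spacing), tol_voxels), offset

    def better(cand_key, best_key) -> bool:
        # maximize score; ties -> smaller total |angle|; then lexicographic
        (s1, a1), (s0, a0) = cand_key, best_key
        t1 = (-s1, sum(abs(v) for v in a1), a1)
        t0 = (-s0, sum(abs(v) for v in a0), a0)
        return t1 < t0

    best_angles = (0.0, 0.0, 0.0)
    best_score, best_offset = score(best_angles)
    if mode == "exhaustive":
        for az in grid:
            for ay in grid:
                for ax in grid:
                    angles = (float(az), float(ay), float(ax))
                    s, off = score(angles)
                    if better((s, angles), (best_score, best_angles)):
                        best_score, best_angles, best_offset = s, angles, off
    elif mode == "sequential":
        current = [0.0, 0.0, 0.0]
        for axis in range(3):
            for a in grid:
                angles = list(current)
                angles[axis] = float(a)
                angles = tuple(angles)
                s, off = score(angles)
                if better((s, angles), (best_score, best_angles)):
                    best_score, best_angles, best_offset = s, angles, off
            current = list(best_angles)
    else:
        raise ValueError(f"unknown search mode: {mode}")
    return best_angles, best_offset, best_score


# ---------------------------------------------------------------------------
# Full segmentation procedures
# ---------------------------------------------------------------------------

_CUBE_STRUCT = np.ones((3, 3, 3), dtype=bool)


def _voi_under_contour(
    candidate: np.ndarray,
    atlas: np.ndarray,
    angles: tuple[float, float, float],
    anchor: np.ndarray,
) -> np.ndarray:
    placed, _ = _place_atlas(atlas, angles, anchor, shape=candidate.shape)
    placed = ndimage.binary_dilation(placed, structure=_CUBE_STRUCT)
    voi = candidate & placed
    return _largest_component(voi)


def segment_voi_metabolic(img: VolumeImage, atlas_mask: BinaryMask,
                          *, search_mode: str = "sequential") -> SegmentationResult:
    """Segment the brain VOI for a uniformly accumulating (metabolic) tracer.

    Pipeline: drop the caudal third, adapt the threshold to an atlas-sized
    connected object, then contour-match the binarized atlas over the
    rotation grid; the VOI is the candidate restricted to the best-placed
    atlas mask (dilated by one voxel).
    """
    work = drop_caudal_third(img)
    target = atlas_mask.count()
    cand_mask, thr = adaptive_volume_threshold(work, target)
    anchor = _centroid(cand_mask.voxels)
    angles, _offset, score = rotation_search(
        cand_mask, atlas_mask, anchor=anchor, mode=search_mode
    )
    voi = _voi_under_contour(cand_mask.voxels, atlas_mask.voxels, angles, anchor)
    return SegmentationResult(BinaryMask(voi, img.spacing), angles, score, thr)


def _morphological_reduction(mask: np.ndarray) -> np.ndarray:
    """Reduce a thresholded head candidate toward the brain support.

    Fill holes, open with a 3x3x3 element, split touching components with a
    distance-transform watershed, and keep the components overlapping the
    central axial band (middle half of the z extent, where the brain lies
    after caudal truncation).

    Hole filling runs in 3-D and additionally per axial slice: a head shell
    truncated at the caudal end is open in 3-D but closed (annular) in most
    axial cross-sections, and the brain interior must become part of the
    candidate volume.
    """
    filled = ndimage.binary_fill_holes(mask)
    for z in range(filled.shape[0]):
        if filled[z].any():
            filled[z] = ndimage.binary_fill_holes(filled[z])
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(filled, structure=_CUBE_STRUCT),
        structure=_CUBE_STRUCT,
    )
    if not opened.any():
        return opened
    dist = ndimage.distance_transform_edt(opened)
    markers, n = ndimage.label(dist > 0.6 * dist.max())
    if n > 1:
        labels = watershed(-dist, markers, mask=opened)
    else:
        labels, _ = ndimage.label(opened)
    nz = mask.shape[0]
    band = slice(nz // 4, max(nz // 4 + 1, 3 * nz // 4))
    keep_ids = np.unique(labels[band])
    keep_ids = keep_ids[keep_ids > 0]
    return np.isin(labels, keep_ids) & opened


def _erode_to_size(mask: np.ndarray, target_voxel_count: int) -> np.ndarray:
    """Erode a solid candidate until it is approximately atlas-sized.

    The filled head volume is larger than the brain; uniform erosion of a
    roughly concentric head converges onto a brain-sized, brain-centred
    object against which the atlas contour match has discriminative power.
    Stops at the last erosion whose largest component still holds at least
    ``target_voxel_count`` voxels.
    """
    current = _largest_component(mask)
    while True:
        nxt = _largest_component(
            ndimage.binary_erosion(current, structure=_FACE_STRUCT, border_value=0)
        )
        if int(nxt.sum()) < target_voxel_count:
            return current
        current = nxt


def _seed_points(interior: np.ndarray, max_seeds: int, min_separation: float = 3.0
                 ) -> list[np.ndarray]:
    """Pick deep interior voxels, greedily spaced apart, as match anchors."""
    if not interior.any():
        return []
    dist = ndimage.distance_transform_edt(interior)
    coords = np.argwhere(interior)
    depths = dist[interior]
    order = np.argsort(depths)[::-1]
    seeds: list[np.ndarray] = []
    for idx in order:
        p = coords[idx].astype(float)
        if all(np.linalg.norm(p - s) >= min_separation for s in seeds):
            seeds.append(p)
        if len(seeds) >= max_seeds:
            break
    return seeds


def segment_voi_target_selective(
    img: VolumeImage,
    atlas_mask: BinaryMask,
    *,
    search_mode: str = "sequential",
    max_seeds: int = 5,
) -> SegmentationResult:
    """Segment the brain VOI for a target-selective (focal-uptake) tracer.

    After caudal truncation and adaptive thresholding the candidate still
    contains non-brain structures of similar intensity, so it is reduced
    morphologically; interior voxels of the reduced volume anchor the atlas
    centroid during the contour-matching rotation search, and the best
    (seed, rotation) pair defines the VOI.
    """
    if not (img.voxels != 0).any():
        raise SegmentationFailure("empty image")
    work = drop_caudal_third(img)
    target = atlas_mask.count()
    thresholded, thr = adaptive_volume_threshold(work, target)
    # hole filling turns a bright head shell into a solid head candidate that
    # contains the dim brain; the atlas is matched inside this volume
    reduced = _morphological_reduction(thresholded.voxels)
    if not reduced.any():
        raise SegmentationFailure("morphological reduction removed everything")
    reduced = _erode_to_size(reduced, target)
    cand_mask = BinaryMask(reduced, img.spacing)
    interior = ndimage.binary_erosion(reduced, structure=_FACE_STRUCT, border_value=0)
    seeds = _seed_points(interior, max_seeds)
    if not seeds:
        raise SegmentationFailure("no interior seed points after reduction")
    best: tuple[float, tuple, np.ndarray] | None = None
    for seed in seeds:
        angles, _offset, score = rotation_search(
            cand_mask, atlas_mask, anchor=seed, mode=search_mode
        )
        if best is None or score > best[0]:
            best = (score, angles, seed)
    score, angles, seed = best
    voi = _voi_under_contour(reduced, atlas_mask.voxels, angles, seed)
    return SegmentationResult(BinaryMask(voi, img.spacing), angles, score, thr)
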