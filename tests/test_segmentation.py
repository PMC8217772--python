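import numpy as np
import pytest
from scipy import ndimage

from nudpa.io_preprocess import BinaryMask, VolumeImage
from nudpa.segmentation import (
    ROTATION_RANGE_DEG,
    ROTATION_STEP_DEG,
    SegmentationFailure,
    adaptive_volume_threshold,
    bf_score,
    drop_caudal_third,
    integer_shift,
    otsu_thresholds,
    rotate_mask,
    rotation_search,
    segment_voi_metabolic,
    segment_voi_target_selective,
)

SPACING = (800.0, 800.0, 800.0)


def _dice(a, b):
    a, b = a.astype(bool), b.astype(bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def test_drop_caudal_third():
    vox = np.ones((9, 4, 4))
    out = drop_caudal_third(VolumeImage(vox, SPACING))
    assert out.voxels[:6].sum() == 6 * 16
    assert out.voxels[6:].sum() == 0  # last floor(9/3) = 3 slices zeroed


def test_otsu_thresholds_bimodal():
    rng = np.random.default_rng(0)
    lo = rng.normal(1, 0.1, 4000)
    hi = rng.normal(5, 0.1, 4000)
    (t,) = otsu_thresholds(np.concatenate([lo, hi]))
    # the threshold separates the two clusters almost perfectly
    assert (lo <= t).mean() > 0.99 and (hi > t).mean() > 0.99
    top = rng.normal(10, 0.1, 4000)
    t1, t2 = otsu_thresholds(np.concatenate([lo, hi, top]), n_thresholds=2)
    assert t1 < t2
    assert (lo <= t1).mean() > 0.99
    assert ((hi > t1) & (hi <= t2)).mean() > 0.99
    assert (top > t2).mean() > 0.99


def test_adaptive_volume_threshold_hits_target():
    # nested intensity shells: the threshold controls the component volume
    zn, yn, xn = np.indices((40, 40, 40)) - 19.5
    r = np.sqrt(zn**2 + yn**2 + xn**2)
    vol = VolumeImage(np.clip(20.0 - r, 0.0, None), SPACING)
    target = 2000
    mask, thr = adaptive_volume_threshold(vol, target)
    assert abs(mask.count() - target) <= 0.2 * target
    assert thr > 0
    # an unreachable target volume fails loudly
    with pytest.raises(SegmentationFailure):
        adaptive_volume_threshold(vol, 40**3 * 2)


def test_rotate_mask_roundtrip():
    mask = np.zeros((20, 20, 20), dtype=bool)
    mask[8:12, 6:14, 9:11] = True
    rot = rotate_mask(mask, (10.0, 0.0, 0.0))
    back = rotate_mask(rot, (-10.0, 0.0, 0.0))
    assert _dice(mask, back) > 0.9
    np.testing.assert_array_equal(rotate_mask(mask, (0.0, 0.0, 0.0)), mask)


def test_integer_shift():
    arr = np.zeros((5, 5, 5))
    arr[2, 2, 2] = 1.0
    out = integer_shift(arr, (1, 0, -1))
    assert out[3, 2, 1] == 1.0 and out.sum() == 1.0
    # content shifted off the edge is cropped, not wrapped
    out = integer_shift(arr, (4, 0, 0))
    assert out.sum() == 0.0


# ---------------------------------------------------------------------------
# BF score
# ---------------------------------------------------------------------------


def _bf_brute_force(a, b, tol):
    """Direct re-implementation: precision/recall over boundary voxels."""

    def boundary(mask):
        er = ndimage.binary_erosion(
            mask, structure=ndimage.generate_binary_structure(3, 1)
        )
        return np.argwhere(mask & ~er)

    pa, pb = boundary(a), boundary(b)
    if len(pa) == 0 and len(pb) == 0:
        return 1.0
    if len(pa) == 0 or len(pb) == 0:
        return 0.0
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    precision = (d.min(axis=1) <= tol).mean()
    recall = (d.min(axis=0) <= tol).mean()
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def test_bf_score_identity_and_disjoint():
    a = np.zeros((12, 12, 12), dtype=bool)
    a[4:8, 4:8, 4:8] = True
    ma = BinaryMask(a, SPACING)
    assert bf_score(ma, ma) == pytest.approx(1.0)
    b = np.zeros_like(a)
    b[0:2, 0:2, 0:2] = True
    assert bf_score(ma, BinaryMask(b, SPACING)) == 0.0
    empty = BinaryMask(np.zeros_like(a), SPACING)
    assert bf_score(empty, empty) == pytest.approx(1.0)
    assert bf_score(ma, empty) == 0.0


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_bf_score_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    a = np.zeros((14, 14, 14), dtype=bool)
    b = np.zeros_like(a)
    ca = rng.integers(4, 10, 3)
    cb = rng.integers(4, 10, 3)
    zn, yn, xn = np.indices(a.shape)
    a[(zn - ca[0]) ** 2 + (yn - ca[1]) ** 2 + (xn - ca[2]) ** 2 <= 16] = True
    b[(zn - cb[0]) ** 2 + (yn - cb[1]) ** 2 + (xn - cb[2]) ** 2 <= 9] = True
    for tol in (1.0, 2.0):
        ours = bf_score(BinaryMask(a, SPACING), BinaryMask(b, SPACING), tol)
        ref = _bf_brute_force(a, b, tol)
        assert ours == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# Rotation search
# ---------------------------------------------------------------------------


def _long_bar_mask():
    """A long notched bar in the (y, x) plane: z-rotations are unambiguous.

    The lever arm must exceed ~30 voxels for the default 1-voxel BF tolerance
    to resolve a 2-degree step (r * sin(2 deg) > 1 voxel).
    """
    m = np.zeros((24, 48, 96), dtype=bool)
    m[8:16, 20:28, 8:88] = True
    m[8:16, 20:24, 8:24] = False  # notch breaks the 180-degree symmetry
    return m


def test_rotation_search_recovers_angle_sequential():
    atlas = BinaryMask(_long_bar_mask(), SPACING)
    cand = rotate_mask(atlas.voxels, (10.0, 0.0, 0.0))
    cand = integer_shift(cand.astype(float), (1, -2, 2)) > 0.5
    angles, offset, score = rotation_search(BinaryMask(cand, SPACING), atlas)
    assert abs(angles[0] - 10.0) <= ROTATION_STEP_DEG
    assert abs(angles[1]) <= ROTATION_STEP_DEG
    assert abs(angles[2]) <= ROTATION_STEP_DEG
    assert offset == (1, -2, 2)
    assert score > 0.9


def _small_l_mask():
    m = np.zeros((24, 24, 24), dtype=bool)
    m[6:18, 9:14, 4:20] = True
    m[6:10, 9:14, 4:9] = False
    m[10:14, 14:17, 6:10] = True
    return m


def test_rotation_search_exhaustive_matches_sequential():
    # a compact mask needs a sharper boundary tolerance to resolve 2 degrees;
    # both search modes must then recover the same (angle, offset)
    atlas = BinaryMask(_small_l_mask(), SPACING)
    cand = rotate_mask(atlas.voxels, (10.0, 0.0, 0.0))
    cand = integer_shift(cand.astype(float), (2, -1, 1)) > 0.5
    cb = BinaryMask(cand, SPACING)
    seq = rotation_search(cb, atlas, mode="sequential", tol_voxels=0.5)
    exh = rotation_search(cb, atlas, mode="exhaustive", tol_voxels=0.5)
    assert exh[2] >= seq[2] - 1e-12  # exhaustive is never worse
    assert abs(exh[0][0] - 10.0) <= ROTATION_STEP_DEG
    assert exh[1] == (2, -1, 1)


def test_rotation_search_identity_is_best():
    atlas = BinaryMask(_small_l_mask(), SPACING)
    angles, offset, score = rotation_search(atlas, atlas)
    assert angles == (0.0, 0.0, 0.0)
    assert offset == (0, 0, 0)
    assert score == pytest.approx(1.0)


def test_rotation_search_grid_limits():
    lo, hi = ROTATION_RANGE_DEG
    assert lo == -20.0 and hi == 20.0 and ROTATION_STEP_DEG == 2.0


# ---------------------------------------------------------------------------
# End-to-end segmentation on the phantom
# ---------------------------------------------------------------------------


def test_segment_voi_metabolic_dice(spec, fractions):
    from nudpa.io_preprocess import sum_frames
    from nudpa.phantoms import make_pet_animal

    img, gt = make_pet_animal(
        spec, fractions, rotation_deg=(6.0, 0.0, 0.0), translation_vox=(2.0, -3.0, 1.0)
    )
    summed = sum_frames(img)
    truth = ndimage.shift(
        rotate_mask(gt.brain_mask.voxels, (6.0, 0.0, 0.0)).astype(float),
        (2.0, -3.0, 1.0), order=0,
    ) > 0.5
    res = segment_voi_metabolic(summed, gt.brain_mask)
    assert _dice(res.voi_mask.voxels, truth) >= 0.9
    # the VOI is one connected component
    n_comp = ndimage.label(res.voi_mask.voxels)[1]
    assert n_comp == 1


def test_segment_voi_target_selective_dice(fractions):
    from nudpa.io_preprocess import sum_frames
    from nudpa.phantoms import PhantomSpec, make_pet_animal

    tspec = PhantomSpec(tracer_mode="target_selective", seed=21, noise_sigma=0.02)
    img, gt = make_pet_animal(
        tspec, fractions, rotation_deg=(8.0, 0.0, 0.0), translation_vox=(1.0, 2.0, -2.0)
    )
    summed = sum_frames(img)
    truth = ndimage.shift(
        rotate_mask(gt.brain_mask.voxels, (8.0, 0.0, 0.0)).astype(float),
        (1.0, 2.0, -2.0), order=0,
    ) > 0.5
    res = segment_voi_target_selective(summed, gt.brain_mask)
    assert _dice(res.voi_mask.voxels, truth) >= 0.8
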