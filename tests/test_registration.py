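import numpy as np
import pytest
from scipy import ndimage

from nudpa.io_preprocess import BinaryMask, DynamicImage, VolumeImage, sum_frames
from nudpa.registration import (
    AlignedSubject,
    RegistrationError,
    Transform,
    TransformChain,
    affine_register,
    align_subject_states,
    apply_transform,
    build_aux_metabolic,
    build_aux_target,
    deformable_register,
    from_sitk,
    gradient_magnitude,
    reference_rigid_register,
    rigid_register,
    similarity_report,
    to_sitk,
)

SPACING = (800.0, 800.0, 800.0)


def _blob_volume(shape=(48, 40, 40), seed=0):
    """A smooth asymmetric blob with internal structure (registrable)."""
    rng = np.random.default_rng(seed)
    zn, yn, xn = np.indices(shape, dtype=float)
    c = np.array(shape) / 2.0
    e = (
        ((zn - c[0]) / 16) ** 2
        + ((yn - c[1] - 3) / 9) ** 2
        + ((xn - c[2]) / 12) ** 2
    )
    vol = np.clip(1.5 - e, 0.0, None)
    lump = ((zn - c[0] - 6) ** 2 + (yn - c[1]) ** 2 + (xn - c[2] - 5) ** 2) < 25
    vol[lump] += 1.0
    vol += 0.01 * rng.normal(size=shape)
    return VolumeImage(np.clip(vol, 0.0, None), SPACING)


def _rigidly_moved(vol, angle_z_deg, shift_vox):
    out = ndimage.rotate(vol.voxels, angle_z_deg, axes=(1, 2), reshape=False,
                         order=1)
    out = ndimage.shift(out, shift_vox, order=1)
    return VolumeImage(np.clip(out, 0.0, None), vol.spacing)


# ---------------------------------------------------------------------------
# Bridging and transform plumbing
# ---------------------------------------------------------------------------


def test_to_from_sitk_roundtrip():
    vol = _blob_volume()
    back = from_sitk(to_sitk(vol))
    np.testing.assert_allclose(back.voxels, vol.voxels)
    np.testing.assert_allclose(back.spacing, vol.spacing)


def test_apply_empty_chain_is_copy():
    vol = _blob_volume()
    out = apply_transform(vol, TransformChain([]))
    np.testing.assert_array_equal(out.voxels, vol.voxels)


def test_chain_frame_compatibility():
    import SimpleITK as sitk

    a = Transform("rigid", sitk.Euler3DTransform(), "B", "A")
    b = Transform("rigid", sitk.Euler3DTransform(), "C", "B")
    TransformChain([a, b])  # A -> B -> C is fine
    with pytest.raises(ValueError):
        TransformChain([b, a])


def test_apply_transform_dynamic_consistency():
    """Each frame receives the identical spatial mapping."""
    vol = _blob_volume()
    t = rigid_register(_rigidly_moved(vol, 4.0, (1, 0, -1)), vol)
    chain = TransformChain([t])
    dyn = DynamicImage(
        np.stack([vol.voxels, 2.0 * vol.voxels]),
        SPACING,
        [(0.0, 600.0), (600.0, 1200.0)],
    )
    out_dyn = apply_transform(dyn, chain)
    out_vol = apply_transform(vol, chain)
    np.testing.assert_allclose(out_dyn.voxels[0], out_vol.voxels, atol=1e-9)
    np.testing.assert_allclose(out_dyn.voxels[1], 2.0 * out_vol.voxels,
                               atol=1e-9)


# ---------------------------------------------------------------------------
# Rigid / affine recovery
# ---------------------------------------------------------------------------


def test_rigid_recovery_against_truth_and_oracle():
    fixed = _blob_volume()
    true_angle, true_shift = 7.0, (2.0, -1.0, 1.0)
    moving = _rigidly_moved(fixed, true_angle, true_shift)

    t = rigid_register(moving, fixed)
    params = t.parameters()
    rot_z = params["rotation_deg"][2]  # sitk order (x, y, z)
    assert abs(abs(rot_z) - true_angle) < 1.0
    # alignment quality: correlation must rise substantially
    aligned = apply_transform(moving, TransformChain([t]))
    before = similarity_report(moving, fixed).pearson
    after = similarity_report(aligned, fixed).pearson
    assert after > before and after > 0.99

    # independent oracle agrees on the angle within its own grid step
    angles, shift = reference_rigid_register(moving, fixed)
    assert abs(abs(angles[0]) - true_angle) <= 1.0


def test_rigid_translation_recovery_subvoxel():
    fixed = _blob_volume(seed=2)
    moving = _rigidly_moved(fixed, 0.0, (1.5, -0.5, 1.0))
    t = rigid_register(moving, fixed)
    tr_um = t.parameters()["translation_um"]  # (x, y, z) in um
    rec_vox = np.array([tr_um[2], tr_um[1], tr_um[0]]) / 800.0  # -> (z, y, x)
    # the transform maps fixed -> moving points, so it carries the shift
    # that was applied to the content
    np.testing.assert_allclose(rec_vox, (1.5, -0.5, 1.0), atol=0.5)


def test_affine_scale_recovery():
    fixed = _blob_volume(seed=3)
    c = (np.array(fixed.voxels.shape) - 1) / 2.0
    mat = np.eye(3) / 1.1  # content enlarged by 10% about the centre
    moving = VolumeImage(
        np.clip(
            ndimage.affine_transform(fixed.voxels, mat, offset=c - mat @ c,
                                     order=1),
            0.0, None,
        ),
        SPACING,
    )
    t = affine_register(moving, fixed, metric="correlation")
    A = np.array(t.parameters()["matrix"]).reshape(3, 3)
    s_rec = np.linalg.det(A) ** (1.0 / 3.0)
    # fixed -> moving mapping: points map onto the enlarged content
    assert s_rec == pytest.approx(1.1, rel=0.02)


def test_rigid_register_rejects_unknown_metric():
    vol = _blob_volume()
    with pytest.raises(ValueError):
        rigid_register(vol, vol, metric="nope")
    with pytest.raises(ValueError):
        affine_register(vol, vol, metric="nope")


# ---------------------------------------------------------------------------
# Deformable
# ---------------------------------------------------------------------------


def test_deformable_register_improves_or_holds_alignment():
    fixed = _blob_volume(seed=4)
    # a mild non-rigid distortion on top of a rigid move
    zn, yn, xn = np.indices(fixed.voxels.shape, dtype=float)
    warp = [zn + 1.2 * np.sin(yn / 8.0), yn, xn - 1.0]
    warped = ndimage.map_coordinates(fixed.voxels, warp, order=1)
    moving = VolumeImage(np.clip(warped, 0.0, None), SPACING)

    t = deformable_register(moving, fixed)
    aligned = apply_transform(moving, TransformChain([t]))
    before = similarity_report(moving, fixed).pearson
    after = similarity_report(aligned, fixed).pearson
    assert t.kind == "deformable"
    assert after > before
    assert after > 0.98


def test_deformable_register_is_deterministic():
    fixed = _blob_volume(seed=5)
    moving = _rigidly_moved(fixed, 3.0, (1.0, 0.0, -1.0))
    a1 = apply_transform(moving, TransformChain([deformable_register(moving, fixed)]))
    a2 = apply_transform(moving, TransformChain([deformable_register(moving, fixed)]))
    np.testing.assert_array_equal(a1.voxels, a2.voxels)


# ---------------------------------------------------------------------------
# Auxiliary structures
# ---------------------------------------------------------------------------


def test_build_aux_metabolic_keeps_hotspots(spec, fractions, clean_animal):
    img, gt = clean_animal
    summed = sum_frames(img)
    aux = build_aux_metabolic(summed, gt.brain_mask)
    # hotspots (intensity 20) survive in the auxiliary volume
    assert aux.voxels.max() > 0.8 * summed.voxels.max()
    # all-zero image is rejected
    with pytest.raises(RegistrationError):
        build_aux_metabolic(VolumeImage(np.zeros((12, 12, 12)), SPACING),
                            gt.brain_mask)


def test_build_aux_target_inverts_voi(fractions):
    from nudpa.phantoms import PhantomSpec, make_pet_animal

    tspec = PhantomSpec(tracer_mode="target_selective", seed=31,
                        noise_sigma=0.02)
    img, gt = make_pet_animal(tspec, fractions)
    summed = sum_frames(img)
    aux = build_aux_target(summed, gt.brain_mask)
    voi = gt.brain_mask.voxels
    # inside the VOI the lesion (brightest spot) must become DIM
    lesion = (summed.voxels == summed.voxels[voi].max()) & voi
    assert aux.voxels[lesion].mean() < np.median(aux.voxels[voi])
    assert aux.voxels.shape == summed.voxels.shape


# ---------------------------------------------------------------------------
# Within-subject alignment
# ---------------------------------------------------------------------------


def test_align_subject_states_recovers_motion(spec, fractions):
    from nudpa.phantoms import make_pet_animal

    img_c, gt = make_pet_animal(spec, fractions)
    img_d, _ = make_pet_animal(spec, fractions, rotation_deg=(5.0, 0.0, 0.0),
                               translation_vox=(2.0, 1.0, -1.0))
    series = {"r1": [("control", img_c), ("lesion", img_d)]}
    aux = lambda v: build_aux_metabolic(v, gt.brain_mask)
    out = align_subject_states(series, aux)
    subj = out["r1"]
    assert isinstance(subj, AlignedSubject)
    assert subj.states == ["control", "lesion"]
    assert subj.chains[0].steps == []  # control is the reference
    before = similarity_report(sum_frames(img_d), sum_frames(img_c)).pearson
    after = similarity_report(
        sum_frames(subj.images[1]), sum_frames(img_c)
    ).pearson
    assert after > before and after > 0.98


def test_align_subject_states_single_state_passthrough(spec, fractions,
                                                       clean_animal):
    img, gt = clean_animal
    series = {"r1": [("control", img)]}
    out = align_subject_states(
        series, lambda v: build_aux_metabolic(v, gt.brain_mask)
    )
    np.testing.assert_array_equal(out["r1"].images[0].voxels, img.voxels)


# ---------------------------------------------------------------------------
# Similarity report
# ---------------------------------------------------------------------------


def test_similarity_report_identity():
    vol = _blob_volume(seed=6)
    rep = similarity_report(vol, vol)
    assert rep.pearson == pytest.approx(1.0)
    assert rep.spearman == pytest.approx(1.0)
    # identical images: MI equals each marginal entropy
    assert rep.mutual_information == pytest.approx(rep.joint_entropy, rel=1e-9)
    assert not rep.degenerate


def test_similarity_report_masked_and_degenerate():
    vol = _blob_volume(seed=7)
    mask = BinaryMask(vol.voxels > 0.5, SPACING)
    rep = similarity_report(vol, vol, mask=mask)
    assert rep.scope == "voi"
    flat = VolumeImage(np.ones_like(vol.voxels), SPACING)
    rep2 = similarity_report(vol, flat)
    assert rep2.degenerate and np.isnan(rep2.pearson)
    with pytest.raises(ValueError):
        similarity_report(vol, VolumeImage(np.ones((2, 2, 2)), SPACING))


def test_gradient_magnitude():
    zn = np.indices((8, 8, 8), dtype=float)[0]
    g = gradient_magnitude(VolumeImage(zn, SPACING))
    np.testing.assert_allclose(g.voxels, 1.0)
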