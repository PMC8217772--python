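"""Synthetic rodent-head phantoms with known ground truth.

Every stage of the pipeline is testable without scanner data: this module
generates a high-resolution ellipsoidal "brain" MRI with a labeled
sub-region atlas (including a caudal cerebellum and a bilateral cortex shell
that can be hemisphere-split), and dynamic PET cohorts in either tracer mode

* metabolic — near-uniform brain uptake plus a pair of bright paraocular
  (Harderian-gland-like) hotspots rostral to the brain;
* target-selective — dim brain, one bright focal lesion inside it, and a
  bright head shell around it;

with known rigid perturbations per animal, a monotone time-activity scaling
across frames, intensity-proportional Gaussian noise (a Poisson surrogate),
and optional multiplicative group effects per region.  All randomness is
drawn from per-animal `numpy` generators spawned deterministically from the
cohort seed, so a fixed seed reproduces the cohort bit for bit.

The phantom deliberately omits PET physics (scatter, randoms, PSF) and
anatomical realism beyond ellipsoid sectors; conclusions from passing tests
concern the pipeline's numerics, not scanner realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .atlas import FractionalAtlas, LabelAtlas, compute_scale_factor, resize_subregions
from .io_preprocess import BinaryMask, DynamicImage, VolumeImage
from .quantify import StudyRecord

REGION_NAMES = {
    1: "cortex",
    2: "cerebellum",
    3: "thalamus",
    4: "striatum",
    5: "hippocampus",
    6: "olfactory",
}


@dataclass
class PhantomSpec:
    """Geometry, uptake and noise model of the synthetic study."""

    mri_shape: tuple[int, int, int] = (160, 128, 128)  # (z, y, x)
    mri_spacing_um: tuple[float, float, float] = (400.0, 400.0, 400.0)
    pet_spacing_um: tuple[float, float, float] = (800.0, 800.0, 800.0)
    #: brain semi-axes in MRI voxels, (z, y, x); longest along z, shortest y
    brain_semiaxes: tuple[float, float, float] = (44.0, 26.0, 34.0)
    #: brain centre in MRI voxels; rostral placement keeps the brain clear of
    #: the caudal third that segmentation discards
    brain_center: tuple[float, float, float] = (62.0, 64.0, 64.0)
    tracer_mode: str = "metabolic"
    brain_uptake: float = 10.0  # kBq/mL-scale arbitrary concentration units
    background_uptake: float = 0.0
    hotspot_contrast: float = 2.0  # Harderian hotspots vs. brain (metabolic)
    lesion_contrast: float = 10.0  # lesion vs. brain (target-selective)
    shell_contrast: float = 5.0  # head shell vs. brain (target-selective)
    lesion_center_offset: tuple[float, float, float] = (-8.0, -4.0, 10.0)
    lesion_radius_vox: float = 8.0  # MRI voxels
    noise_sigma: float = 0.05  # relative, scaled by sqrt(intensity)
    n_frames: int = 6
    frame_length_s: float = 600.0
    #: per-state multiplicative uptake effects, state -> {region_id: factor}
    group_effects: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        c = np.array(self.brain_center)
        a = np.array(self.brain_semiaxes)
        if np.any(c - a < 0) or np.any(c + a >= np.array(self.mri_shape)):
            raise ValueError("brain ellipsoid does not fit inside the MRI grid")
        if self.tracer_mode not in ("metabolic", "target_selective"):
            raise ValueError(f"unknown tracer mode: {self.tracer_mode}")


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    rotation_deg: tuple[float, float, float]  # about (z, y, x)
    translation_vox: tuple[float, float, float]  # PET voxels (z, y, x)
    region_means: dict[int, float]  # noise-free fraction-weighted means
    brain_mask: BinaryMask  # unperturbed PET-grid brain support
    uptake_volume: VolumeImage  # noise-free, unperturbed concentration


# ---------------------------------------------------------------------------
# Atlas phantom
# ---------------------------------------------------------------------------


def _ellipsoid_coords(shape, center, semiaxes):
    z, y, x = np.indices(shape, dtype=np.float64)
    zn = (z - center[0]) / semiaxes[0]
    yn = (y - center[1]) / semiaxes[1]
    xn = (x - center[2]) / semiaxes[2]
    return zn, yn, xn, zn * zn + yn * yn + xn * xn


def make_atlas_phantom(spec: PhantomSpec) -> tuple[VolumeImage, LabelAtlas]:
    """High-resolution T2*-like volume and labeled atlas.

    The brain ellipsoid is partitioned into six disjoint sectors: a caudal
    cerebellum cap, a rostral olfactory tip, a dorsal cortex shell (bilateral,
    splittable at the sagittal midline), a ventral hippocampus shell, and
    central thalamus/striatum blocks.  The T2* image is a per-region base
    intensity plus a smooth random field.
    """
    zn, yn, xn, r2 = _ellipsoid_coords(
        spec.mri_shape, spec.brain_center, spec.brain_semiaxes
    )
    inside = r2 <= 1.0
    labels = np.zeros(spec.mri_shape, dtype=np.int32)
    shell = r2 > 0.49  # outer shell; inner core at r < 0.7
    dorsal = yn < 0
    # core: thalamus (caudal half) / striatum (rostral half)
    core = inside & ~shell
    labels[core & (zn > 0)] = 3
    labels[core & (zn <= 0)] = 4
    # shell sectors
    labels[inside & shell & dorsal] = 1  # cortex
    labels[inside & shell & ~dorsal] = 5  # hippocampus
    # caps override shells
    labels[inside & (zn > 0.55)] = 2  # cerebellum (caudal)
    labels[inside & (zn < -0.62)] = 6  # olfactory (rostral)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
    base = {0: 0.0, 1: 0.9, 2: 0.7, 3: 0.5, 4: 0.55, 5: 0.8, 6: 0.6}
    t2 = np.zeros(spec.mri_shape)
    for rid, b in base.items():
        t2[labels == rid] = b
    smooth = ndimage.gaussian_filter(rng.normal(0, 1, spec.mri_shape), sigma=6)
    t2 = np.clip(t2 + 0.05 * smooth * inside, 0, None)
    mri = VolumeImage(t2, spec.mri_spacing_um)
    atlas = LabelAtlas(labels, spec.mri_spacing_um, dict(REGION_NAMES))
    return mri, atlas


def pet_fractional_atlas(spec: PhantomSpec, atlas: LabelAtlas | None = None
                         ) -> FractionalAtlas:
    """The phantom atlas resampled onto the PET grid."""
    if atlas is None:
        _, atlas = make_atlas_phantom(spec)
    rs = compute_scale_factor(spec.pet_spacing_um[1], spec.mri_spacing_um[1])
    return resize_subregions(atlas, rs)


# ---------------------------------------------------------------------------
# PET cohort
# ---------------------------------------------------------------------------


def _pet_uptake_volume(
    spec: PhantomSpec,
    fractions: FractionalAtlas,
    effects: dict[int, float],
) -> np.ndarray:
    """Noise-free concentration on the PET grid from fractional memberships."""
    shape = fractions.brain_mask.voxels.shape
    conc = np.full(shape, float(spec.background_uptake))
    total = fractions.total_fraction()
    conc *= np.clip(1.0 - total, 0.0, 1.0)  # background only outside brain

    if spec.tracer_mode == "metabolic":
        brain_level = spec.brain_uptake
    else:
        brain_level = spec.brain_uptake / spec.lesion_contrast  # dim brain
    for rid, frac in fractions.fractions.items():
        conc += frac * brain_level * float(effects.get(rid, 1.0))

    f = spec.pet_spacing_um[1] / spec.mri_spacing_um[1]
    center = np.array(spec.brain_center) / f
    semi = np.array(spec.brain_semiaxes) / f

    if spec.tracer_mode == "metabolic":
        # Harderian-gland-like pair: small bright spheres rostral to the brain
        for side in (-1.0, 1.0):
            c = center + np.array([-semi[0] - 3.0, 2.0, side * semi[2] * 0.55])
            _, _, _, r2 = _ellipsoid_coords(shape, c, (2.5, 2.5, 2.5))
            conc[r2 <= 1.0] = spec.brain_uptake * spec.hotspot_contrast
    else:
        # bright head shell surrounding the brain
        _, _, _, r2o = _ellipsoid_coords(shape, center, semi * 1.45)
        _, _, _, r2i = _ellipsoid_coords(shape, center, semi * 1.25)
        shell = (r2o <= 1.0) & (r2i > 1.0)
        shell[int(center[0] + semi[0] * 1.6):] = False  # open caudally (neck)
        conc[shell] = np.maximum(conc[shell], brain_level * spec.shell_contrast)
        # focal lesion inside the brain
        lc = center + np.array(spec.lesion_center_offset) / f
        _, _, _, r2l = _ellipsoid_coords(shape, lc, (spec.lesion_radius_vox / f,) * 3)
        conc[r2l <= 1.0] = brain_level * spec.lesion_contrast
    return conc


def _apply_rigid(vol: np.ndarray, rotation_deg, translation_vox) -> np.ndarray:
    out = vol
    planes = [(1, 2), (0, 2), (0, 1)]
    for plane, ang in zip(planes, rotation_deg):
        if ang:
            out = ndimage.rotate(out, ang, axes=plane, reshape=False, order=1,
                                 mode="constant", cval=0.0)
    if any(translation_vox):
        out = ndimage.shift(out, translation_vox, order=1, mode="constant", cval=0.0)
    return out


def _time_activity_weights(n_frames: int) -> np.ndarray:
    # monotone rising uptake across frames, normalized to mean 1
    w = 1.0 + 0.15 * np.arange(n_frames)
    return w / w.mean()


def make_pet_animal(
    spec: PhantomSpec,
    fractions: FractionalAtlas,
    *,
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    translation_vox: tuple[float, float, float] = (0.0, 0.0, 0.0),
    effects: dict[int, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DynamicImage, GroundTruth]:
    """One dynamic PET acquisition with a known rigid perturbation."""
    effects = effects or {}
    rng = rng or np.random.default_rng(spec.seed)
    conc = _pet_uptake_volume(spec, fractions, effects)
    clean = VolumeImage(conc, spec.pet_spacing_um)

    total = fractions.total_fraction()
    region_means = {}
    for rid, frac in fractions.fractions.items():
        denom = float(frac.sum())
        region_means[rid] = float((frac * conc).sum() / denom) if denom else 0.0

    moved = _apply_rigid(conc, rotation_deg, translation_vox)
    weights = _time_activity_weights(spec.n_frames)
    frames = np.empty((spec.n_frames,) + conc.shape)
    for i, w in enumerate(weights):
        f = moved * w
        if spec.noise_sigma > 0:
            sigma = spec.noise_sigma * np.sqrt(np.maximum(f, 0.0) * f.max())
            f = np.clip(f + rng.normal(0.0, 1.0, f.shape) * sigma, 0.0, None)
        frames[i] = f
    schedule = [
        (i * spec.frame_length_s, (i + 1) * spec.frame_length_s)
        for i in range(spec.n_frames)
    ]
    img = DynamicImage(frames, spec.pet_spacing_um, schedule)
    gt = GroundTruth(
        tuple(rotation_deg), tuple(translation_vox), region_means,
        BinaryMask(fractions.brain_mask.voxels.copy(), spec.pet_spacing_um), clean,
    )
    return img, gt


def make_pet_cohort(
    spec: PhantomSpec,
    n_animals: int,
    states: list[str] = ("control",),
    *,
    max_rotation_deg: float = 8.0,
    max_translation_vox: float = 4.0,
) -> list[tuple[str, str, DynamicImage, StudyRecord, GroundTruth]]:
    """A cohort of animals, each measured in every state.

    Per (animal, state), a rigid perturbation is drawn uniformly within the
    stated bounds, the state's group effects are applied, and frames receive
    intensity-proportional noise from a per-animal RNG stream spawned from
    the cohort seed.  Returns (animal_id, state, image, record, truth) rows.
    """
    _, atlas = make_atlas_phantom(spec)
    fractions = resize_subregions(
        atlas,
        compute_scale_factor(spec.pet_spacing_um[1], spec.mri_spacing_um[1]),
    )
    rows = []
    for i in range(n_animals):
        for j, state in enumerate(states):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, i, j])
            )
            rot = tuple(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
            tra = tuple(rng.uniform(-max_translation_vox, max_translation_vox, 3))
            effects = dict(spec.group_effects.get(state, {}))
            img, gt = make_pet_animal(
                spec, fractions,
                rotation_deg=rot, translation_vox=tra,
                effects=effects, rng=rng,
            )
            record = StudyRecord(
                animal_id=f"Rat_No_{i + 1}",
                group="phantom",
                state=state,
                injected_activity_bq=float(31e6 + rng.normal(0, 3e6)),
                body_weight_g=float(rng.uniform(250, 300)),
                tracer_mode=spec.tracer_mode,
            )
            rows.append((record.animal_id, state, img, record, gt))
    return rows


# ---------------------------------------------------------------------------
# Direct quantification-level cohorts (for statistical calibration)
# ---------------------------------------------------------------------------


def simulate_quant_table(
    n_subjects: int,
    states: list[str],
    region_means: dict[str, float],
    *,
    effects: dict[str, dict[str, float]] | None = None,
    cv: float = 0.1,
    seed: int = 0,
    parameter: str = "UR",
    interval: str = "0-60 min",
):
    """A tidy quantification table sampled directly from region means.

    Used for statistical calibration experiments (many replicate cohorts)
    where running the imaging pipeline per cohort would be pointless: values
    are region means times the state's effect, with lognormal-like subject
    variation of coefficient ``cv``.
    """
    import pandas as pd

    effects = effects or {}
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        subj_factor = float(np.exp(rng.normal(0.0, cv / 2)))
        for state in states:
            for region, mean in region_means.items():
                eff = effects.get(state, {}).get(region, 1.0)
                value = mean * eff * subj_factor * float(
                    np.exp(rng.normal(0.0, cv))
                )
                rows.append(
                    {
                        "animal_id": f"S{i + 1}",
                        "group": "sim",
                        "state": state,
                        "region": region,
                        "region_id": 0,
                        "interval": interval,
                        "parameter": parameter,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)
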