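"""Config-driven end-to-end orchestration of the analysis.

From imported dynamic PET images (or a generated phantom cohort) the pipeline
runs automatically: preprocessing, atlas resampling, VOI segmentation of the
control group, template construction, within-subject and template alignment
(optionally through a second template), co-registration to the MRI atlas,
per-region quantification and group statistics.  Every stage leaves QC
artifacts (masks, similarity CSV rows, transform JSON) in the output
directory, and a run manifest records the configuration, seed and package
version so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    LabelAtlas,
    compute_scale_factor,
    read_atlas,
    read_label_table,
    resize_subregions,
    resize_volume,
    split_region_hemispheres,
)
from .io_preprocess import (
    BinaryMask,
    DynamicImage,
    VolumeImage,
    detect_repeat_measurements,
    exclude_peripheral_slices,
    group_intensity_factors,
    read_volume,
    remove_speckles,
    sum_frames,
    write_volume,
)
from .quantify import WHOLE_VOI, StudyRecord, quantify_cohort
from .registration import (
    AlignedSubject,
    TransformChain,
    align_subject_states,
    align_to_template,
    apply_transform,
    build_aux_metabolic,
    build_aux_target,
    coregister_to_mri,
    similarity_report,
)
from .segmentation import (
    segment_voi_metabolic,
    segment_voi_target_selective,
)
from .stats import run_region_stats
from .template import (
    Template,
    build_template,
    second_template_workflow,
    segment_template_voi,
    select_reference,
)

logger = logging.getLogger("nudpa.pipeline")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    output_dir: str
    tracer_mode: str = "metabolic"
    pet_inplane_res_um: float = 800.0
    mri_res_um: float = 400.0
    intervals: list[tuple[float, float]] = field(default_factory=lambda: [(0.0, 60.0)])
    reference_region: str | int = WHOLE_VOI
    paired: bool = True
    seed: int = 0
    n_peripheral_slices: int = 5
    second_template: bool = False
    second_template_group: str | None = None
    split_region: str | None = None  # region name to hemisphere-split
    search_mode: str = "sequential"
    statistics_parameters: tuple[str, ...] = ("UR",)
    # file inputs (exclusive with `phantom`)
    images: list[dict] = field(default_factory=list)
    mri_path: str | None = None
    atlas_path: str | None = None
    label_table_path: str | None = None
    # phantom inputs
    phantom: dict | None = None

    def validate(self) -> None:
        errors = []
        if self.tracer_mode not in ("metabolic", "target_selective"):
            errors.append(f"tracer_mode must be metabolic|target_selective, "
                          f"got {self.tracer_mode!r}")
        if self.pet_inplane_res_um <= 0 or self.mri_res_um <= 0:
            errors.append("resolutions must be positive")
        for iv in self.intervals:
            if len(iv) != 2 or iv[0] >= iv[1]:
                errors.append(f"malformed interval {iv}")
        if self.phantom is None:
            if not self.images:
                errors.append("either `phantom` or `images` must be given")
            if self.mri_path is None or self.atlas_path is None:
                errors.append("mri_path and atlas_path are required with file input")
            for p in (self.mri_path, self.atlas_path, self.label_table_path):
                if p is not None and not Path(p).exists():
                    errors.append(f"path does not exist: {p}")
            required = {"path", "name", "state", "injected_activity_bq",
                        "body_weight_g"}
            for entry in self.images:
                missing = required - set(entry)
                if missing:
                    errors.append(f"image entry missing fields {sorted(missing)}")
                elif not Path(entry["path"]).exists():
                    errors.append(f"path does not exist: {entry['path']}")
        if self.second_template and self.second_template_group is None:
            errors.append("second_template requires second_template_group")
        if errors:
            raise ConfigError("invalid configuration:\n- " + "\n- ".join(errors))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file and check all cross-references."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.intervals = [tuple(iv) for iv in cfg.intervals]
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------


def _load_inputs(cfg: PipelineConfig):
    """Return (mri, atlas, records, images) from files or the phantom."""
    if cfg.phantom is not None:
        from .phantoms import PhantomSpec, make_atlas_phantom, make_pet_cohort

        ph = dict(cfg.phantom)
        n_animals = int(ph.pop("n_animals", 3))
        states = list(ph.pop("states", ["control"]))
        spec = PhantomSpec(tracer_mode=cfg.tracer_mode, seed=cfg.seed, **ph)
        mri, atlas = make_atlas_phantom(spec)
        rows = make_pet_cohort(spec, n_animals, states)
        records, images = {}, {}
        for name, state, img, rec, _gt in rows:
            key = f"{name}:{state}"
            records[key] = rec
            images[key] = img
        return mri, atlas, records, images
    table = read_label_table(cfg.label_table_path) if cfg.label_table_path else None
    atlas = read_atlas(cfg.atlas_path, table)
    mri_dyn = read_volume(cfg.mri_path)
    mri = VolumeImage(mri_dyn.voxels[0], mri_dyn.spacing)
    records, images = {}, {}
    for entry in cfg.images:
        key = f"{entry['name']}:{entry['state']}"
        records[key] = StudyRecord(
            animal_id=entry["name"],
            group=entry.get("group", "default"),
            state=entry["state"],
            injected_activity_bq=float(entry["injected_activity_bq"]),
            body_weight_g=float(entry["body_weight_g"]),
            tracer_mode=cfg.tracer_mode,
        )
        images[key] = read_volume(entry["path"])
    return mri, atlas, records, images


def _segment(cfg: PipelineConfig, img: VolumeImage, atlas_mask: BinaryMask):
    if cfg.tracer_mode == "metabolic":
        return segment_voi_metabolic(img, atlas_mask, search_mode=cfg.search_mode)
    return segment_voi_target_selective(img, atlas_mask, search_mode=cfg.search_mode)


#: checkpoints accepted by ``run_pipeline(stop_after=...)``, in stage order
STAGE_CHECKPOINTS = ("segment", "template", "align", "quantify")


def run_pipeline(cfg: PipelineConfig, *, stop_after: str | None = None) -> Path:
    """Execute all stages; returns the output directory.

    Stage order: preprocess -> atlas resample -> segment control VOIs ->
    template (reference by VOI orientation, deformable members) -> align
    within subject, then to the template (optionally through a second,
    rigid-only template) -> co-register to MRI -> quantify on original
    dynamic frames -> group statistics.

    ``stop_after`` ends the run after the named checkpoint (one of
    ``STAGE_CHECKPOINTS``), leaving the artifacts produced so far in the
    output directory.
    """
    if stop_after is not None and stop_after not in STAGE_CHECKPOINTS:
        raise ConfigError(
            f"stop_after must be one of {STAGE_CHECKPOINTS}, got {stop_after!r}"
        )
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    qc = out / "qc"
    qc.mkdir(exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    np.random.seed(cfg.seed % (2**31))

    mri, atlas, records, images = _load_inputs(cfg)
    if cfg.split_region is not None:
        rid = next(
            (k for k, v in atlas.label_table.items() if v == cfg.split_region), None
        )
        if rid is None:
            raise ConfigError(f"split_region {cfg.split_region!r} not in atlas")
        atlas = split_region_hemispheres(atlas, rid)

    # ---- preprocessing -------------------------------------------------
    logger.info("stage: preprocessing (%d images)", len(images))
    pre: dict[str, DynamicImage] = {}
    for key, img in images.items():
        if img.voxels.shape[1] > 2 * cfg.n_peripheral_slices + 2:
            img = exclude_peripheral_slices(img, cfg.n_peripheral_slices)
        img, _rep = remove_speckles(img)
        pre[key] = img
    summed = {key: sum_frames(img) for key, img in pre.items()}

    groups: dict[str, list[str]] = {}
    for key, rec in records.items():
        groups.setdefault(rec.group, []).append(key)
    factors: dict[str, float] = {}
    for keys in groups.values():
        fs = group_intensity_factors([summed[k] for k in keys])
        factors.update(dict(zip(keys, fs)))
    normed = {
        k: VolumeImage(summed[k].voxels * factors[k], summed[k].spacing)
        for k in summed
    }

    series_spec = [(records[k].animal_id, records[k].group, records[k].state)
                   for k in records]
    series_states = detect_repeat_measurements(series_spec)

    # ---- atlas resampling ----------------------------------------------
    logger.info("stage: atlas resampling")
    rspec = compute_scale_factor(cfg.pet_inplane_res_um, cfg.mri_res_um)
    fractions = resize_subregions(atlas, rspec)
    mri_resized = resize_volume(mri, rspec)
    atlas_mask = fractions.brain_mask
    write_volume(atlas_mask, qc / "atlas_brain_mask.nii.gz")

    # ---- control-VOI segmentation and template -------------------------
    logger.info("stage: VOI segmentation + template")
    key_of = {}
    for key, rec in records.items():
        key_of[(rec.animal_id, rec.state)] = key
    control_keys = [key_of[(n, states[0])] for n, states in series_states.items()]
    segs = {k: _segment(cfg, normed[k], atlas_mask) for k in control_keys}
    for k, s in segs.items():
        write_volume(s.voi_mask, qc / f"voi_{k.replace(':', '_')}.nii.gz")
    if stop_after == "segment":
        return out
    masks = [segs[k].voi_mask for k in control_keys]
    ref = select_reference(masks)
    template = build_template(
        [normed[k] for k in control_keys], masks, ref, member_ids=control_keys
    )
    template = segment_template_voi(
        template, atlas_mask, cfg.tracer_mode, search_mode=cfg.search_mode
    )
    write_volume(template.image, out / "template.nii.gz")
    write_volume(template.voi_mask, out / "template_voi.nii.gz")
    if stop_after == "template":
        return out

    # ---- alignment ------------------------------------------------------
    logger.info("stage: alignment")
    if cfg.tracer_mode == "metabolic":
        aux_builder = lambda vol: build_aux_metabolic(vol, atlas_mask)  # noqa: E731
    else:
        def aux_builder(vol, _segs={}):
            res = segment_voi_target_selective(vol, atlas_mask,
                                               search_mode=cfg.search_mode)
            return build_aux_target(vol, res.voi_mask)

    series_imgs = {
        name: [(state, pre[key_of[(name, state)]]) for state in states]
        for name, states in series_states.items()
    }
    subjects = align_subject_states(series_imgs, aux_builder)

    sim_rows = []
    if cfg.second_template and cfg.second_template_group:
        in_group = {
            n: s for n, s in subjects.items()
            if records[key_of[(n, s.states[0])]].group == cfg.second_template_group
        }
        rest = {n: s for n, s in subjects.items() if n not in in_group}
        aligned = align_to_template(rest, template.image) if rest else {}
        second_aligned, second = second_template_workflow(
            in_group, template, atlas_mask, aux_builder,
            search_mode=cfg.search_mode,
        )
        aligned.update(second_aligned)
        if second is not None:
            write_volume(second.image, out / "template2.nii.gz")
    else:
        aligned = align_to_template(subjects, template.image)

    for name, subj in aligned.items():
        after = sum_frames(subj.images[0])
        sim_rows.append(
            {"subject": name, **similarity_report(
                after, template.image, scope="full-image", phase="after").as_row()}
        )
    if stop_after == "align":
        pd.DataFrame(sim_rows).to_csv(out / "similarity.csv", index=False)
        return out

    # ---- co-registration to MRI/atlas ----------------------------------
    logger.info("stage: co-registration")
    coreg = coregister_to_mri(template.image, template.voi_mask,
                              mri_resized, atlas_mask)
    for i, step in enumerate(coreg.steps):
        step.to_json(qc / f"coreg_step{i + 1}.json")

    # ---- quantification (original dynamic frames) -----------------------
    logger.info("stage: quantification")
    atlas_space: dict[str, DynamicImage] = {}
    rec_by_key: dict[str, StudyRecord] = {}
    for name, subj in aligned.items():
        for state, chain in zip(subj.states, subj.chains):
            key = key_of[(name, state)]
            full = TransformChain(list(chain.steps) + list(coreg.steps)) \
                if chain.steps else TransformChain(list(coreg.steps))
            atlas_space[key] = apply_transform(pre[key], full,
                                               reference=mri_resized)
            rec_by_key[key] = records[key]
    ref_region = cfg.reference_region
    if isinstance(ref_region, str) and ref_region != WHOLE_VOI:
        rid = next((k for k, v in fractions.label_table.items() if v == ref_region),
                   None)
        if rid is None:
            raise ConfigError(f"reference region {ref_region!r} not in atlas")
        ref_region = rid
    quant = quantify_cohort(atlas_space, fractions, rec_by_key, cfg.intervals,
                            reference_region=ref_region)
    quant.to_csv(out / "quantification.csv")
    if stop_after == "quantify":
        pd.DataFrame(sim_rows).to_csv(out / "similarity.csv", index=False)
        return out

    # ---- statistics ------------------------------------------------------
    logger.info("stage: statistics")
    n_states = max(len(s.states) for s in aligned.values())
    stats_table = pd.DataFrame()
    if n_states >= 2 or len({r.group for r in records.values()}) >= 2:
        stats_table = run_region_stats(
            quant.table,
            group_column="state" if cfg.paired else "group",
            paired=cfg.paired,
            parameters=cfg.statistics_parameters,
            plot_dir=out / "plots",
        )
        stats_table.to_csv(out / "statistics.csv", index=False)
    pd.DataFrame(sim_rows).to_csv(out / "similarity.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_images": len(images),
        "scale_factor": f"{rspec.scale_factor}",
        "template_reference": template.reference_id,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return out
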