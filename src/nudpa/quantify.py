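"""Semi-quantitative tracer-uptake parameters per atlas sub-region.

Three parameters are computed per region, frame interval and animal, using
the fractional (partial-volume aware) region membership as weights:

* normalized activity ``A_N = region activity / injected activity``
  (dimensionless),
* standardized uptake value
  ``SUV = region concentration / (injected activity / body weight)``
  (g/mL),
* uptake ratio ``UR = region activity / reference activity`` where the
  reference is either the whole VOI or a designated reference region such as
  the cerebellum (dimensionless; the whole-VOI denominator is inappropriate
  when large parts of the brain are themselves affected).

Quantification always reads the original dynamic frames — never the summed,
group-normalized images used for alignment — so A_N and SUV keep their
physical scale.  Interval boundaries must tile whole frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import FractionalAtlas
from .io_preprocess import DynamicImage, VolumeImage

WHOLE_VOI = "whole_voi"


@dataclass
class StudyRecord:
    animal_id: str
    group: str
    state: str
    injected_activity_bq: float
    body_weight_g: float
    tracer_mode: str = "metabolic"

    def __post_init__(self) -> None:
        if self.injected_activity_bq <= 0:
            raise ValueError("injected activity must be positive")
        if self.body_weight_g <= 0:
            raise ValueError("body weight must be positive")
        if self.tracer_mode not in ("metabolic", "target_selective"):
            raise ValueError(f"unknown tracer mode: {self.tracer_mode}")


@dataclass
class QuantResult:
    """Tidy table of per-(animal, region, interval) parameter values."""

    table: pd.DataFrame
    reference_region_used: int | str = WHOLE_VOI

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def wide(self, parameter: str) -> pd.DataFrame:
        sub = self.table[self.table["parameter"] == parameter]
        return sub.pivot_table(
            index=["animal_id", "group", "state", "interval"],
            columns="region",
            values="value",
        ).reset_index()


def voxel_volume_ml(spacing_um: tuple[float, float, float]) -> float:
    """Voxel volume in millilitres from per-axis spacing in micrometres."""
    um3 = float(np.prod(spacing_um))
    return um3 * 1e-12  # 1 mL = 1 cm^3 = 1e12 um^3


def region_activity(
    img_frame: VolumeImage, fractions: FractionalAtlas, region: int
) -> tuple[float, float]:
    """Fraction-weighted activity (Bq) and volume (mL) of one region.

    ``activity = sum_v fraction_r(v) * concentration(v) * voxel_volume``;
    negative concentrations (interpolation undershoot) are clamped to zero
    before aggregation.
    """
    if region not in fractions.fractions:
        raise KeyError(f"region {region} not in fractional atlas")
    frac = fractions.fractions[region]
    conc = np.maximum(img_frame.voxels, 0.0)
    vv = voxel_volume_ml(img_frame.spacing)
    activity = float((frac * conc).sum() * vv)
    volume = float(frac.sum() * vv)
    return activity, volume


def whole_voi_activity(
    img_frame: VolumeImage, fractions: FractionalAtlas
) -> tuple[float, float]:
    """Activity and volume under the summed region fractions (whole VOI)."""
    total = fractions.total_fraction()
    conc = np.maximum(img_frame.voxels, 0.0)
    vv = voxel_volume_ml(img_frame.spacing)
    return float((total * conc).sum() * vv), float(total.sum() * vv)


def normalized_activity(region_activity_bq: float, injected_bq: float) -> float:
    """A_N: fraction of the injected activity measured in the region."""
    if injected_bq <= 0:
        raise ValueError("injected activity must be positive")
    return region_activity_bq / injected_bq


def suv(region_concentration_bq_ml: float, injected_bq: float, body_weight_g: float) -> float:
    """SUV in g/mL: concentration over injected activity per body weight."""
    if injected_bq <= 0 or body_weight_g <= 0:
        raise ValueError("injected activity and body weight must be positive")
    return region_concentration_bq_ml / (injected_bq / body_weight_g)


def uptake_ratio(region_activity_bq: float, reference_activity_bq: float) -> float:
    """UR: region activity over whole-VOI or reference-region activity."""
    if reference_activity_bq <= 0:
        raise ValueError("reference activity must be positive")
    return region_activity_bq / reference_activity_bq


def _frames_for_interval(
    schedule: Sequence[tuple[float, float]], start_s: float, end_s: float
) -> list[int]:
    idx = [i for i, (s, e) in enumerate(schedule) if s >= start_s and e <= end_s]
    covered = sum(schedule[i][1] - schedule[i][0] for i in idx)
    boundaries = sorted({b for s, e in schedule for b in (s, e)})
    if not idx or covered != end_s - start_s or \
            start_s not in boundaries or end_s not in boundaries:
        raise ValueError(
            f"interval [{start_s/60:g}, {end_s/60:g}) min does not tile whole "
            f"frames; valid boundaries (min): {[b/60 for b in boundaries]}"
        )
    return idx


def sum_interval(img: DynamicImage, start_min: float, end_min: float) -> VolumeImage:
    """Sum the frames inside a [start, end) interval given in minutes."""
    idx = _frames_for_interval(img.frame_schedule, start_min * 60.0, end_min * 60.0)
    return VolumeImage(img.voxels[idx].sum(axis=0), img.spacing)


def quantify_cohort(
    images: dict[str, DynamicImage],
    fractions: FractionalAtlas,
    records: dict[str, StudyRecord],
    intervals: Sequence[tuple[float, float]],
    *,
    reference_region: int | str = WHOLE_VOI,
    ur_on_concentration: bool = False,
) -> QuantResult:
    """Compute A_N, SUV and UR for every region, interval and animal.

    ``images`` maps a measurement key (animal/state) to its aligned dynamic
    image in atlas space; ``records`` maps the same keys to study metadata.
    ``reference_region`` selects the UR denominator (a region id, or the
    whole VOI); ``ur_on_concentration`` switches UR to a concentration ratio
    (SUVR-like) instead of the default activity ratio.
    """
    rows = []
    region_ids = sorted(fractions.fractions)
    for key, img in images.items():
        rec = records[key]
        for start_min, end_min in intervals:
            frame = sum_interval(img, start_min, end_min)
            acts: dict[int, tuple[float, float]] = {
                rid: region_activity(frame, fractions, rid) for rid in region_ids
            }
            whole_act, whole_volume = whole_voi_activity(frame, fractions)
            if reference_region == WHOLE_VOI:
                ref_act, ref_vol = whole_act, whole_volume
            else:
                ref_act, ref_vol = acts[reference_region]
            interval_label = f"{start_min:g}-{end_min:g} min"
            for rid in region_ids:
                act, vol = acts[rid]
                conc = act / vol if vol > 0 else float("nan")
                if ur_on_concentration:
                    ref_conc = ref_act / ref_vol if ref_vol > 0 else float("nan")
                    ur = (conc / ref_conc) if ref_conc else float("nan")
                else:
                    ur = uptake_ratio(act, ref_act)
                values = {
                    "A_N": normalized_activity(act, rec.injected_activity_bq),
                    "SUV": suv(conc, rec.injected_activity_bq, rec.body_weight_g),
                    "UR": ur,
                }
                for param, value in values.items():
                    rows.append(
                        {
                            "animal_id": rec.animal_id,
                            "group": rec.group,
                            "state": rec.state,
                            "region": fractions.region_name(rid),
                            "region_id": rid,
                            "interval": interval_label,
                            "parameter": param,
                            "value": value,
                        }
                    )
    table = pd.DataFrame(rows)
    return QuantResult(table, reference_region)
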