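"""Resampling of the high-resolution MRI atlas onto the PET grid.

A stereotaxic MRI T2*-weighted image and its co-registered integer-label
atlas are far finer than the PET grid (tens of micrometres vs. close to a
millimetre).  A single scale factor is derived from the resolution ratio and
the T2* image plus every atlas sub-region are downsampled with trilinear
interpolation.  Resampling each sub-region's indicator volume separately
yields, at every PET voxel, the fraction of that voxel occupied by each
sub-region — a fractional (partial-volume aware) atlas that quantification
uses as weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .io_preprocess import BinaryMask, FormatError, VolumeImage

#: fractions below this are dropped from the sparse per-region storage
SPARSE_FRACTION_CUTOFF = 1e-3


@dataclass
class LabelAtlas:
    """Integer-label atlas volume; 0 denotes background."""

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_table: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        if self.labels.min() < 0:
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels missing from label table: {sorted(missing)}")

    def region_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})


@dataclass
class ResamplingSpec:
    """Atlas-to-PET resize factor; interpolation is always trilinear."""

    scale_factor: Fraction
    method: str = "linear"

    def __post_init__(self) -> None:
        self.scale_factor = Fraction(self.scale_factor)
        if not (0 < self.scale_factor <= 1):
            raise ValueError("scale factor must be in (0, 1]")


@dataclass
class FractionalAtlas:
    """Per-region fractional occupancy on the PET grid.

    ``fractions[region_id]`` is a dense 3-D array of per-voxel membership
    fractions in [0, 1]; values below :data:`SPARSE_FRACTION_CUTOFF` are
    stored as exact zero.  ``brain_mask`` is the binary support of the whole
    resized volume (total fraction > 0.5).
    """

    fractions: dict[int, np.ndarray]
    brain_mask: BinaryMask
    spacing: tuple[float, float, float]
    label_table: dict[int, str] = field(default_factory=dict)

    def total_fraction(self) -> np.ndarray:
        out = np.zeros(self.brain_mask.voxels.shape)
        for frac in self.fractions.values():
            out += frac
        return out

    def region_name(self, region_id: int) -> str:
        return self.label_table.get(region_id, str(region_id))


def read_label_table(path: str | Path) -> dict[int, str]:
    """Read a two-column tab-separated (id, name) label table."""
    table: dict[int, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"malformed label-table line: {line!r}")
        table[int(parts[0])] = parts[1]
    return table


def read_atlas(path: str | Path, label_table: dict[int, str] | None = None) -> LabelAtlas:
    """Read an integer-label atlas from NIfTI/ANALYZE."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: atlas must be 3-D")
    labels = np.transpose(np.rint(data).astype(np.int32), (2, 1, 0))
    sx, sy, sz = (float(z) * 1000.0 for z in img.header.get_zooms()[:3])
    table = label_table
    if table is None:
        table = {int(v): str(int(v)) for v in np.unique(labels) if v != 0}
    return LabelAtlas(labels, (sz, sy, sx), table)


def compute_scale_factor(pet_inplane_res_um: float, mri_res_um: float) -> ResamplingSpec:
    """Scale factor 1/round(PET/MRI resolution ratio).

    The PET in-plane resolution divided by the (isotropic) MRI resolution,
    rounded to the nearest integer, gives the denominator of the resize
    factor — e.g. 776 um PET vs. 39 um MRI gives 1/20.
    """
    if pet_inplane_res_um <= 0 or mri_res_um <= 0:
        raise ValueError("resolutions must be positive")
    ratio = pet_inplane_res_um / mri_res_um
    if ratio < 1:
        raise ValueError(
            "MRI resolution coarser than PET is unsupported "
            f"(ratio {ratio:.3f} < 1)"
        )
    denom = int(round(ratio))
    return ResamplingSpec(Fraction(1, denom))


def _zoom_linear(vol: np.ndarray, factor: float) -> np.ndarray:
    # grid_mode=True treats voxels as cells so the field of view is preserved,
    # matching image-resize semantics of downsampling by a factor.
    return ndimage.zoom(
        np.asarray(vol, dtype=np.float64),
        factor,
        order=1,
        mode="grid-constant",
        grid_mode=True,
        prefilter=False,
    )


def resize_volume(vol: VolumeImage, spec: ResamplingSpec) -> VolumeImage:
    """Trilinearly downsample a volume by the scale factor on every axis."""
    f = float(spec.scale_factor)
    out_shape = tuple(int(round(s * f)) for s in vol.voxels.shape)
    if any(s < 1 for s in out_shape):
        raise ValueError(f"degenerate output shape {out_shape}")
    if spec.scale_factor == 1:
        return VolumeImage(vol.voxels.copy(), vol.spacing)
    data = _zoom_linear(vol.voxels, f)
    new_spacing = tuple(s / f for s in vol.spacing)
    return VolumeImage(data, new_spacing)


def resize_subregions(atlas: LabelAtlas, spec: ResamplingSpec) -> FractionalAtlas:
    """Resample each sub-region's indicator separately to fractional occupancy.

    Linearity of trilinear interpolation guarantees the per-region fractions
    sum to the resized whole-volume indicator at every voxel (partition of
    unity over the resized support).
    """
    region_ids = atlas.region_ids()
    if not region_ids:
        raise ValueError("atlas has no nonzero region")
    f = float(spec.scale_factor)
    new_spacing = tuple(s / f for s in atlas.spacing)
    fractions: dict[int, np.ndarray] = {}
    total = None
    for rid in region_ids:
        frac = _zoom_linear(atlas.labels == rid, f)
        np.clip(frac, 0.0, 1.0, out=frac)
        frac[frac < SPARSE_FRACTION_CUTOFF] = 0.0
        fractions[rid] = frac
        total = frac.copy() if total is None else total + frac
    brain = BinaryMask(total > 0.5, new_spacing)
    return FractionalAtlas(fractions, brain, new_spacing, dict(atlas.label_table))


def split_region_hemispheres(
    atlas: LabelAtlas, region_id: int, midline_axis: int = 2
) -> LabelAtlas:
    """Split one region into left/right halves at its bounding-box midplane.

    Needed when an atlas ships a bilateral structure (e.g. the cortex) as one
    label but the analysis must distinguish hemispheres.  New labels are
    appended to the label table as ``<name>_left`` / ``<name>_right``; by the
    radiological file convention the lower-coordinate half along the
    left-right axis is "right".
    """
    mask = atlas.labels == region_id
    if not mask.any():
        raise ValueError(f"region {region_id} absent from atlas")
    coords = np.nonzero(mask)[midline_axis]
    mid = (coords.min() + coords.max() + 1) / 2.0
    axis_coord = np.indices(atlas.labels.shape)[midline_axis]
    right = mask & (axis_coord < mid)
    left = mask & ~right
    new_labels = atlas.labels.copy()
    next_id = int(atlas.labels.max()) + 1
    right_id, left_id = next_id, next_id + 1
    new_labels[right] = right_id
    new_labels[left] = left_id
    name = atlas.label_table.get(region_id, str(region_id))
    table = dict(atlas.label_table)
    table.pop(region_id, None)
    table[right_id] = f"{name}_right"
    table[left_id] = f"{name}_left"
    if not right.any() or not left.any():
        warnings.warn(
            f"region {region_id} lies entirely on one side of its midline",
            stacklevel=2,
        )
    return LabelAtlas(new_labels, atlas.spacing, table)
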