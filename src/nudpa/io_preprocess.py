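"""Volume I/O and preprocessing applied before alignment.

Dynamic small-animal PET volumes are imported from NIfTI-1 or ANALYZE 7.5
files, peripheral axial slices with poor signal-to-noise are removed, speckle
voxels (spurious single annihilation events) are eliminated by a 26-neighbor
count rule, frames are summed into a single alignment volume, and per-group
intensity normalization factors are computed to compensate for differences in
injected activity.  The summed, normalized images are used only for spatial
alignment; quantification always reads the original dynamic frames.

Conventions fixed here and relied on downstream:

* Voxel arrays are ordered ``(frame, z, y, x)`` for dynamic images and
  ``(z, y, x)`` for single volumes; the axial (slice) axis is ``z`` and the
  caudal direction is increasing ``z``.
* Spacing is per-axis voxel size in micrometres, ordered ``(z, y, x)``.
* Frame intervals are half-open ``[start, end)`` in seconds.
* Voxel values are treated as scanner-calibrated activity concentration
  (Bq/mL); no decay correction is applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised when a file cannot be read as a volumetric image."""


class DegenerateInputError(ValueError):
    """Raised when an input is too small or empty for the requested step."""


class AmbiguityError(ValueError):
    """Raised when study records cannot be grouped unambiguously."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class DynamicImage:
    """A 4-D PET acquisition: stack of frames on a common voxel grid.

    Parameters
    ----------
    voxels:
        Intensity grid ordered ``(frame, z, y, x)``.
    spacing:
        Voxel size in micrometres, ordered ``(z, y, x)``.
    frame_schedule:
        Half-open ``(start_s, end_s)`` intervals, one per frame, sorted and
        non-overlapping.
    meta:
        Free-form provenance (file path, subject name, ...).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    frame_schedule: list[tuple[float, float]]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4 or self.voxels.size == 0:
            raise ValueError("dynamic image must be a non-empty 4-D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")
        if len(self.frame_schedule) != self.voxels.shape[0]:
            raise ValueError("frame schedule length must equal frame count")
        prev_end = -np.inf
        for start, end in self.frame_schedule:
            if start < prev_end or end <= start:
                raise ValueError("frame intervals must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[1:]


@dataclass
class VolumeImage:
    """A single 3-D volume (e.g. a frame-summed PET image)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("volume must be a non-empty 3-D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")


@dataclass
class BinaryMask:
    """A boolean 3-D mask on the same grid contract as the image it masks."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("mask must be a non-empty 3-D grid")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be positive")

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclass
class PreprocessReport:
    """Bookkeeping emitted by the preprocessing steps."""

    n_slices_removed: int = 0
    n_speckle_voxels_removed: int = 0
    multiplication_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.multiplication_factor <= 0:
            raise ValueError("multiplication factor must be positive")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_volume(path: str | Path) -> DynamicImage:
    """Read a NIfTI-1 or ANALYZE 7.5 volume as a :class:`DynamicImage`.

    3-D files are promoted to a single-frame dynamic image.  Spacing is taken
    from the header and converted to micrometres; the frame schedule is taken
    from the header TR when present, otherwise unit-length frames are assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # nibabel raises several error types
        raise FormatError(f"cannot read {path} as NIfTI/ANALYZE: {exc}") from exc
    if data.ndim == 3:
        # file axis order (x, y, z) -> internal (frame, z, y, x)
        data = np.transpose(data, (2, 1, 0))[np.newaxis]
    elif data.ndim == 4:
        # file axis order (x, y, z, t) -> internal (t, z, y, x)
        data = np.transpose(data, (3, 2, 1, 0))
    else:
        raise FormatError(f"{path}: expected 3 or 4 dimensions, got {data.ndim}")

    zooms = img.header.get_zooms()
    if len(zooms) < 3 or any(z <= 0 for z in zooms[:3]):
        raise FormatError(f"{path}: header has no valid voxel spacing")
    unit_to_um = {"unknown": 1000.0, "meter": 1_000_000.0, "mm": 1000.0, "micron": 1.0}
    try:
        space_unit = unit_to_um.get(img.header.get_xyzt_units()[0], 1000.0)
    except Exception:
        space_unit = 1000.0  # mm is the de-facto default
    sx, sy, sz = (float(z) * space_unit for z in zooms[:3])
    spacing = (sz, sy, sx)

    n_frames = data.shape[0]
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    schedule = [(i * tr, (i + 1) * tr) for i in range(n_frames)]
    return DynamicImage(data, spacing, schedule, meta={"source": str(path)})


def write_volume(vol: VolumeImage | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI-1; masks are stored as uint8."""
    data = vol.voxels
    dtype = np.uint8 if isinstance(vol, BinaryMask) else np.float32
    # internal (z, y, x) -> file (x, y, z)
    arr = np.transpose(data, (2, 1, 0)).astype(dtype)
    sz, sy, sx = vol.spacing
    affine = np.diag([sx / 1000.0, sy / 1000.0, sz / 1000.0, 1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def exclude_peripheral_slices(img: DynamicImage, n: int = 5) -> DynamicImage:
    """Drop the first and last ``n`` axial slices of every frame.

    The peripheral slices of the reconstructed field of view carry the worst
    signal-to-noise and are excluded before any further processing.
    """
    nz = img.voxels.shape[1]
    if nz <= 2 * n:
        raise DegenerateInputError(
            f"axial extent {nz} too small to remove 2x{n} slices"
        )
    return DynamicImage(
        img.voxels[:, n : nz - n],
        img.spacing,
        list(img.frame_schedule),
        dict(img.meta),
    )


_NEIGHBORHOOD_26 = np.ones((3, 3, 3), dtype=np.int16)
_NEIGHBORHOOD_26[1, 1, 1] = 0


def remove_speckles(
    img: DynamicImage, min_neighbors: int = 5
) -> tuple[DynamicImage, PreprocessReport]:
    """Zero out foreground voxels with too few 26-connected foreground neighbors.

    The frame-summed image defines the binary foreground; a foreground voxel
    whose 26-neighborhood contains fewer than ``min_neighbors`` foreground
    voxels is treated as a speckle (isolated annihilation events) and zeroed
    in all frames.  The neighbor counts are evaluated once on the original
    mask — the filter is a single pass, not iterated.
    """
    summed = img.voxels.sum(axis=0)
    fg = summed != 0
    counts = ndimage.convolve(
        fg.astype(np.int16), _NEIGHBORHOOD_26, mode="constant", cval=0
    )
    speckle = fg & (counts < min_neighbors)
    out = img.voxels.copy()
    out[:, speckle] = 0.0
    report = PreprocessReport(n_speckle_voxels_removed=int(speckle.sum()))
    return (
        DynamicImage(out, img.spacing, list(img.frame_schedule), dict(img.meta)),
        report,
    )


def sum_frames(img: DynamicImage) -> VolumeImage:
    """Sum all frames into one volume.  Used for alignment only."""
    return VolumeImage(img.voxels.sum(axis=0), img.spacing)


def group_intensity_factors(
    summed_images: Sequence[VolumeImage], mode: str = "all-voxels"
) -> list[float]:
    """Per-image multiplication factors equalizing mean intensity in a group.

    For image *i* with mean intensity ``m_i`` the factor is
    ``max_j(m_j) / m_i``; the brightest image receives factor 1 and applying
    the factors equalizes all group means.  This compensates variation in the
    injected activity between animals of one experimental group.

    ``mode`` selects whether the mean runs over all voxels (default) or only
    the nonzero foreground.
    """
    if not summed_images:
        raise DegenerateInputError("need at least one image per group")
    means = []
    for vol in summed_images:
        v = vol.voxels
        if mode == "nonzero-only":
            v = v[v != 0]
        m = float(v.mean()) if v.size else 0.0
        if m == 0:
            raise DegenerateInputError("image with zero mean intensity")
        means.append(m)
    top = max(means)
    return [top / m for m in means]


def detect_repeat_measurements(
    records: Sequence[tuple[str, str, str]],
    control_states: Sequence[str] = ("control", "healthy", "sham"),
) -> dict[str, list[str]]:
    """Group (name, group, state) records into longitudinal series.

    Records sharing a name form one series, ordered with the control-like
    state first (matched case-insensitively against ``control_states``) and
    the remaining states in input order.
    """
    if any(not name for name, _, _ in records):
        raise AmbiguityError("record with empty name")
    seen: set[tuple[str, str]] = set()
    series: dict[str, list[str]] = {}
    for name, _group, state in records:
        key = (name, state)
        if key in seen:
            raise AmbiguityError(f"duplicate (name, state) pair: {key}")
        seen.add(key)
        series.setdefault(name, []).append(state)
    lowered = tuple(s.lower() for s in control_states)
    for name, states in series.items():
        states.sort(key=lambda s: (s.lower() not in lowered,))
    return series
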