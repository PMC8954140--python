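"""Domain containers, EMIDEC label conventions and NIfTI plumbing.

Label encoding follows the EMIDEC ground-truth convention:
0 background, 1 LV cavity, 2 LV myocardium, 3 MI scar, 4 MVO.
Shapes are (rows, cols, slices); voxel indexing is 0-based; geometry beyond
the voxel spacing (mm) is not tracked because every metric in the pipeline
is a spacing-scaled voxel computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

BACKGROUND, CAVITY, MYOCARDIUM, SCAR, MVO = 0, 1, 2, 3, 4
VALID_LABELS = (BACKGROUND, CAVITY, MYOCARDIUM, SCAR, MVO)
#: classes forming the myocardial wall (healthy muscle plus pathology)
WALL_CLASSES = (MYOCARDIUM, SCAR, MVO)
PATHOLOGY_CLASSES = (SCAR, MVO)

STRUCTURE_NAMES = {CAVITY: "cavity", MYOCARDIUM: "myocardium",
                   SCAR: "scar", MVO: "mvo"}


class ValidationError(ValueError):
    """Raised when a label grid violates the encoding contract."""


@dataclass
class Volume:
    """A 3D intensity grid with mm voxel spacing.

    ``origin_shape`` and ``crop_offset`` record where the grid sits on the
    original scanner grid when a crop has been applied; they are what
    :func:`lgeseg.preprocess.restore_geometry` needs to invert the crop.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin_shape: tuple[int, int, int] | None = None
    crop_offset: tuple[int, int] = (0, 0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume contains NaN/Inf intensities")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        if self.origin_shape is None:
            self.origin_shape = tuple(int(s) for s in self.data.shape)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class LabelMap:
    """Integer class grid sharing the geometry of its :class:`Volume`."""

    labels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValidationError(f"label map must be 3D, got shape {arr.shape}")
        bad = np.setdiff1d(np.unique(arr), VALID_LABELS)
        if bad.size:
            raise ValidationError(f"label values outside {{0..4}}: {bad.tolist()}")
        self.labels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)


@dataclass
class TopologyReport:
    """Counts of nesting violations in a label map.

    pathology_outside_wall
        pathology voxels (scar/MVO) not inside the hole-filled myocardial
        region, where the region is the union of {myocardium, scar, MVO}
        connected components that contain at least one healthy-myocardium
        voxel (a pathology island floating in the background therefore
        counts as a violation).
    mvo_detached_voxels
        voxels of MVO components with no scar voxel inside or touching the
        component (26-connectivity).
    mvo_without_scar
        1 if the map has MVO voxels but no scar voxels at all, else 0.
    """

    pathology_outside_wall: int
    mvo_detached_voxels: int
    mvo_without_scar: int

    def total(self) -> int:
        return (self.pathology_outside_wall + self.mvo_detached_voxels
                + self.mvo_without_scar)

    def is_clean(self) -> bool:
        return self.total() == 0


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def check_topology(labels: LabelMap | np.ndarray) -> TopologyReport:
    """Report nesting violations (pathology ⊂ wall, MVO attached to scar)."""
    arr = labels.labels if isinstance(labels, LabelMap) else np.asarray(labels)
    wall = arr >= MYOCARDIUM
    myo = arr == MYOCARDIUM
    scar = arr == SCAR
    mvo = arr == MVO
    pathology = arr >= SCAR

    comp, n = ndimage.label(wall, structure=_CONN26)
    keep = np.zeros(n + 1, dtype=bool)
    if n:
        has_myo = ndimage.labeled_comprehension(
            myo, comp, np.arange(1, n + 1), np.any, bool, False)
        keep[1:] = has_myo
    region = keep[comp]
    if region.any():
        region = ndimage.binary_fill_holes(region)
    outside = int(np.count_nonzero(pathology & ~region))

    detached = 0
    mcomp, mn = ndimage.label(mvo, structure=_CONN26)
    for i in range(1, mn + 1):
        cm = mcomp == i
        halo = ndimage.binary_dilation(cm, structure=_CONN26)
        if not (halo & scar).any():
            detached += int(cm.sum())

    orphan_case = int(mvo.any() and not scar.any())
    return TopologyReport(outside, detached, orphan_case)


def structure_volume(labels: LabelMap | np.ndarray, class_id: int,
                     spacing: tuple[float, float, float] | None = None) -> float:
    """Volume in mm³ of one structure: voxel count × dx·dy·dz."""
    if isinstance(labels, LabelMap):
        arr, sp = labels.labels, labels.spacing
    else:
        arr, sp = np.asarray(labels), None
    if spacing is not None:
        sp = spacing
    if sp is None:
        raise ValueError("spacing required when labels is a bare array")
    if class_id not in VALID_LABELS[1:]:
        raise ValueError(f"class_id must be in 1..4, got {class_id}")
    return float(np.count_nonzero(arr == class_id)) * float(np.prod(sp))


# ---------------------------------------------------------------------------
# NIfTI plumbing

def _label_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + "_gt" + ext)
    raise IOError(f"not a NIfTI path: {path}")


def read_volume(path) -> tuple[Volume, LabelMap | None]:
    """Read a NIfTI volume and, when a ``*_gt`` sibling exists, its labels."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = Volume(data=data, spacing=spacing)

    labels = None
    lp = _label_path(path)
    if lp.exists():
        limg = nib.load(str(lp))
        larr = np.asarray(limg.dataobj)
        if not np.allclose(larr, np.round(larr)):
            raise ValidationError(f"label file {lp} holds non-integer values")
        labels = LabelMap(labels=np.round(larr).astype(np.int64), spacing=spacing)
    return vol, labels


def write_volume(volume: Volume, labels: LabelMap | None, path) -> None:
    """Write a volume (and optional labels, as uint8) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if labels is not None and labels.shape != volume.shape:
        raise ValidationError(
            f"label shape {labels.shape} != volume shape {volume.shape}")
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))
    if labels is not None:
        nib.save(nib.Nifti1Image(labels.labels.astype(np.uint8), affine),
                 str(_label_path(path)))
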