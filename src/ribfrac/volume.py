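"""Spatial data model and NIfTI I/O.

Every stage of the pipeline works on dense 3D arrays with per-axis voxel
spacing in millimetres. Axis order is fixed package-wide as (L, W, H) with
0-based indices; ``spacing[i]`` is the physical extent of one voxel along
array axis ``i``. The affine from the source NIfTI header is carried along
for provenance but never used to resample or reorder axes: a voxel at index
(i, j, k) on disk is at (i, j, k) in memory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "BinaryMask3D",
    "NormalizedVolume",
    "read_nifti",
    "write_nifti",
]

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three strictly positive values, got {spacing}")
    return spacing


@dataclasses.dataclass
class CTVolume:
    """A CT scan in Hounsfield units.

    Attributes
    ----------
    voxels : (L, W, H) float array of HU intensities, all finite.
    spacing : mm per voxel along each array axis.
    affine : 4x4 voxel-to-world matrix from the source header (provenance only).
    id : scan identifier.
    """

    voxels: np.ndarray
    spacing: Spacing
    affine: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D image, got rank {self.voxels.ndim}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CT volume contains non-finite voxels")
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclasses.dataclass
class BinaryMask3D:
    """A {0,1} voxel mask aligned voxel-for-voxel with a :class:`CTVolume`."""

    voxels: np.ndarray
    spacing: Spacing
    affine: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError(f"expected 3D image, got rank {arr.ndim}")
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"mask values must be in {{0,1}}, got {vals[:10]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.voxels.sum())


@dataclasses.dataclass
class NormalizedVolume:
    """A volume linearly mapped into [0, 1] (network input)."""

    voxels: np.ndarray
    spacing: Spacing
    affine: np.ndarray | None = None
    id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3D image, got rank {self.voxels.ndim}")
        lo, hi = float(self.voxels.min(initial=0.0)), float(self.voxels.max(initial=0.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"normalized volume out of [0,1]: min={lo}, max={hi}")
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


def read_nifti(path: str | Path, kind: str = "volume") -> CTVolume | BinaryMask3D:
    """Read a NIfTI-1/2 file as a CT volume or a binary mask.

    For ``kind="mask"`` any nonzero integer label is collapsed to 1; masks with
    non-integer values are rejected. The scan id defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D image, got rank {data.ndim} in {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    scan_id = path.name.removesuffix(".gz").removesuffix(".nii")
    if kind == "volume":
        return CTVolume(data.astype(np.float32), spacing, np.asarray(img.affine), scan_id)
    if kind == "mask":
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"mask contains non-integer labels: {path}")
        return BinaryMask3D((data != 0).astype(np.uint8), spacing, np.asarray(img.affine), scan_id)
    raise ValueError(f"kind must be 'volume' or 'mask', got {kind!r}")


def write_nifti(obj: CTVolume | BinaryMask3D | NormalizedVolume, path: str | Path) -> None:
    """Write a volume or mask to NIfTI, storing spacing in the header zooms.

    Masks are stored as uint8, volumes as float32; a write-then-read round trip
    reproduces voxels bit-exactly for masks and to float32 precision otherwise.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(obj, BinaryMask3D):
        data = obj.voxels.astype(np.uint8)
    else:
        data = obj.voxels.astype(np.float32)
    affine = obj.affine if obj.affine is not None else np.diag([*obj.spacing, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, str(path))
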