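"""The raw imaging object: a 3D grid of integer Hounsfield units.

Axis order is fixed as (z, y, x), 0-based, with per-axis spacing in mm.
NIfTI I/O transposes to/from the on-disk (x, y, z) order so that spacing
follows its axis through the round trip.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np

HU_MIN = -1024
HU_MAX = 3071


@dataclasses.dataclass
class AttenuationVolume:
    """3D integer-HU grid with voxel spacing.

    Parameters
    ----------
    voxels
        Integer HU values, shape (nz, ny, nx), all within [-1024, 3071].
    spacing
        Voxel edge lengths in mm, ordered (z, y, x); all strictly positive.
    origin
        Informational offset in mm; not used by any computation.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError("voxels must be an integer array (HU convention)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        lo, hi = int(self.voxels.min()), int(self.voxels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(
                f"HU values out of range [{HU_MIN}, {HU_MAX}]: found [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3 (product of spacings)."""
        return float(np.prod(self.spacing))

    def save_nifti(self, path: str | Path) -> None:
        """Write the volume as NIfTI with spacing in the header."""
        _save_nifti(self.voxels.astype(np.int16), self.spacing, path)

    @classmethod
    def load_nifti(cls, path: str | Path) -> "AttenuationVolume":
        data, spacing = _load_nifti(path)
        return cls(voxels=np.rint(data).astype(np.int16), spacing=spacing)


def _save_nifti(array_zyx: np.ndarray, spacing_zyx, path: str | Path) -> None:
    # NIfTI stores (x, y, z); affine diagonal carries the spacing.
    data_xyz = np.ascontiguousarray(array_zyx.transpose(2, 1, 0))
    sz, sy, sx = spacing_zyx
    affine = np.diag([sx, sy, sz, 1.0])
    nib.save(nib.Nifti1Image(data_xyz, affine), str(path))


def _load_nifti(path: str | Path):
    img = nib.load(str(path))
    data_xyz = np.asanyarray(img.dataobj)
    sx, sy, sz = img.header.get_zooms()[:3]
    return data_xyz.transpose(2, 1, 0), (float(sz), float(sy), float(sx))


def save_mask_nifti(mask_zyx: np.ndarray, spacing_zyx, path: str | Path) -> None:
    """Write a boolean mask as uint8 NIfTI."""
    _save_nifti(mask_zyx.astype(np.uint8), spacing_zyx, path)


def load_mask_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a uint8 NIfTI mask; returns (bool array (z,y,x), spacing)."""
    data, spacing = _load_nifti(path)
    return data.astype(bool), spacing
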