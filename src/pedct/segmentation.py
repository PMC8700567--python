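"""Threshold-based lung segmentation with exterior-air removal.

An attenuation window selects air-like voxels; 6-connected components that
touch a lateral (x or y) grid face are discarded as exterior air, as are
components below a minimum volume. The z faces are deliberately exempt:
cranial/caudal slices may legitimately truncate lung. Central airways stay
inside the mask.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from pedct.volume import AttenuationVolume

DEFAULT_WINDOW = (-1024, -200)
DEFAULT_MIN_COMPONENT_ML = 5.0

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class EmptyWindowError(ValueError):
    """No voxel fell inside the attenuation window."""


class SegmentationError(RuntimeError):
    """No lung component survived exterior-air and size filtering."""


@dataclasses.dataclass
class LungMask:
    """Boolean voxel mask congruent with its source volume."""

    voxels: np.ndarray
    component_count: int

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.voxels.any():
            raise ValueError("mask must be nonempty")


def select_attenuation_window(
    volume: AttenuationVolume, lower: float = DEFAULT_WINDOW[0], upper: float = DEFAULT_WINDOW[1]
) -> np.ndarray:
    """Boolean mask of voxels with lower <= HU <= upper (inclusive)."""
    if lower >= upper:
        raise ValueError(f"window lower bound must be < upper, got ({lower}, {upper})")
    mask = (volume.voxels >= lower) & (volume.voxels <= upper)
    if not mask.any():
        raise EmptyWindowError(f"no voxels in window [{lower}, {upper}]")
    return mask


def remove_external_air(
    candidate_mask: np.ndarray,
    volume: AttenuationVolume,
    min_component_mL: float = DEFAULT_MIN_COMPONENT_ML,
) -> LungMask:
    """Drop exterior-air and sub-minimum components from a candidate mask.

    Components are 6-connected. A component touching any x or y face of the
    grid is exterior air; one smaller than ``min_component_mL`` is noise.
    Idempotent: applying it to its own output changes nothing.
    """
    candidate_mask = np.asarray(candidate_mask, dtype=bool)
    if candidate_mask.shape != volume.shape:
        raise ValueError("candidate mask and volume shapes differ")
    if not candidate_mask.any():
        raise ValueError("candidate mask is empty")

    labels, n_labels = ndimage.label(candidate_mask, structure=_STRUCT6)

    touches_lateral = np.zeros(n_labels + 1, dtype=bool)
    for face in (labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]):
        touches_lateral[np.unique(face)] = True

    sizes = np.bincount(labels.ravel(), minlength=n_labels + 1)
    min_voxels = min_component_mL * 1000.0 / volume.voxel_volume_mm3
    keep = ~touches_lateral & (sizes >= min_voxels)
    keep[0] = False

    if not keep.any():
        raise SegmentationError(
            "no lung component retained after exterior-air and size filtering"
        )
    return LungMask(voxels=keep[labels], component_count=int(keep.sum()))


def mask_volume_mL(mask: LungMask | np.ndarray, volume: AttenuationVolume) -> float:
    """Voxel count x voxel volume, in mL."""
    voxels = mask.voxels if isinstance(mask, LungMask) else np.asarray(mask, dtype=bool)
    if voxels.shape != volume.shape:
        raise ValueError("mask and volume shapes differ")
    return float(voxels.sum()) * volume.voxel_volume_mm3 / 1000.0


def segment_lungs(
    volume: AttenuationVolume,
    window: tuple[float, float] = DEFAULT_WINDOW,
    min_component_mL: float = DEFAULT_MIN_COMPONENT_ML,
) -> LungMask:
    """Full pipeline: attenuation window, then exterior-air removal."""
    candidate = select_attenuation_window(volume, *window)
    return remove_external_air(candidate, volume, min_component_mL=min_component_mL)
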