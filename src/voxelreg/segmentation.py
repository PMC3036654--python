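"""Threshold-based bone segmentation (3D model construction step).

Bony tissue is selected by a lower Hounsfield-unit threshold: every voxel at
or above the threshold enters the mask.  Clinically the threshold is chosen
per scan in the 250-350 HU range; the default here is the midpoint, 300 HU.
Optional post-processing keeps the largest 26-connected component and/or
removes small islands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, Volume


class EmptySegmentationError(RuntimeError):
    """Raised when thresholding (after post-processing) selects no voxels."""


@dataclass
class SegmentationConfig:
    lower_hu: float = 300.0
    keep_largest: bool = False
    min_island_voxels: int = 0

    def __post_init__(self) -> None:
        if not (-1000.0 <= self.lower_hu <= 3000.0):
            raise ValueError(f"lower threshold {self.lower_hu} HU outside sane range [-1000, 3000]")
        if self.min_island_voxels < 0:
            raise ValueError("min_island_voxels must be >= 0")


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_bone(volume: Volume, config: SegmentationConfig | None = None) -> BinaryMask:
    """Mask of voxels with intensity >= the lower threshold (inclusive).

    Raises :class:`EmptySegmentationError` if nothing survives, rather than
    silently returning an empty model.
    """
    config = config or SegmentationConfig()
    data = np.asarray(volume.data)
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite intensities")
    mask = data >= config.lower_hu

    if mask.any() and (config.keep_largest or config.min_island_voxels > 0):
        labels, n = ndimage.label(mask, structure=_CONN26)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        if config.keep_largest:
            mask = labels == int(np.argmax(sizes))
        elif config.min_island_voxels > 0:
            keep = np.flatnonzero(sizes >= config.min_island_voxels)
            mask = np.isin(labels, keep)

    if not mask.any():
        raise EmptySegmentationError(
            f"no voxels at or above {config.lower_hu} HU after post-processing"
        )
    return BinaryMask.like(volume, mask)


def mask_statistics(mask: BinaryMask) -> dict:
    """Voxel count, physical volume (mm³) and world bounding box of a mask."""
    count = int(mask.data.sum())
    voxel_volume = float(np.prod(mask.spacing))
    if count == 0:
        return {"count": 0, "volume_mm3": 0.0, "bbox_min_mm": None, "bbox_max_mm": None}
    idx = np.argwhere(mask.data)
    lo = mask.origin + mask.axes @ (mask.spacing * idx.min(axis=0))
    hi = mask.origin + mask.axes @ (mask.spacing * idx.max(axis=0))
    return {
        "count": count,
        "volume_mm3": count * voxel_volume,
        "bbox_min_mm": np.minimum(lo, hi),
        "bbox_max_mm": np.maximum(lo, hi),
    }
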