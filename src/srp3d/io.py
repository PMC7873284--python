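"""Volume I/O and nucleus cropping.

Volumes are multi-page grayscale TIFF stacks.  In memory the axis order is
``(x, y, z)`` with z the page index; integer data is converted to float on
read.  Cropping takes a precomputed integer label mask (0 = background)
and returns per-object bounding-box sub-volumes with out-of-object voxels
zeroed, so descriptors are not diluted by background.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import List, Tuple

import numpy as np
import tifffile
from scipy import ndimage

__all__ = ["read_volume", "write_volume", "crop_objects"]


def read_volume(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF as a float ``(x, y, z)`` array."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: expected a single-channel stack, got shape {arr.shape}"
        )
    if arr.shape[-1] in (3, 4) and arr.ndim == 3 and arr.shape[0] > 8:
        # heuristically a (H, W, C) color image rather than a short stack
        raise ValueError(f"{path}: color TIFFs are not supported")
    # pages arrive as (z, y, x); reorder to (x, y, z)
    return np.asarray(arr, dtype=float).transpose(2, 1, 0)


def write_volume(path: str | Path, volume: np.ndarray) -> None:
    """Write an ``(x, y, z)`` array as a multi-page grayscale TIFF."""
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"volume must be 3D, got shape {volume.shape}")
    tifffile.imwrite(
        str(path), volume.transpose(2, 1, 0), photometric="minisblack"
    )


def crop_objects(
    volume: np.ndarray,
    label_mask: np.ndarray,
    pad: int = 0,
) -> List[Tuple[np.ndarray, int]]:
    """Crop each labelled object to its padded bounding box.

    Boxes are half-open and clipped at the volume bounds; voxels inside a
    crop that belong to another label or to background are zeroed.  An
    empty mask yields an empty list with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    label_mask = np.asarray(label_mask)
    if volume.shape != label_mask.shape:
        raise ValueError(
            f"mask shape {label_mask.shape} != volume shape {volume.shape}"
        )
    labels = np.unique(label_mask)
    labels = labels[labels != 0]
    if labels.size == 0:
        warnings.warn("label mask is empty; no objects to crop", stacklevel=2)
        return []
    crops = []
    slices = ndimage.find_objects(label_mask)
    for lab in labels:
        sl = slices[int(lab) - 1]
        if sl is None:
            continue
        padded = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, volume.shape)
        )
        sub = volume[padded].copy()
        sub[label_mask[padded] != lab] = 0.0
        crops.append((sub, int(lab)))
    return crops
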