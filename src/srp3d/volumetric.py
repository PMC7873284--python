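"""Cubic-patch volumetric texture descriptors built from in-patch hyperplanes.

A volume is tiled into ``5 x 5 x z`` cubic patches.  Within each patch,
2D sampling planes ("hyperplanes") connect every column of the bottom
slice with every column of the top slice along 3D Bresenham lines, for the
YZ and XZ lateral families; the XY family is the axial slices themselves.
Each plane is a 5x5 grid fed to :mod:`srp3d.srp_core`; the five projected
function value sets are pooled per plane family and binned into 16-bin
L1-normalized histograms, giving an 80-dim block per family and a 240-dim
descriptor per patch.  The pseudo-3D variant keeps only the XY family
(80-dim), ignoring interslice correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from srp3d.srp_core import (
    PATTERN_NAMES,
    RPBank,
    extract_pattern_matrix,
)

__all__ = [
    "VolumePatch",
    "CubicPatchDescriptor",
    "VolumeDescriptorSet",
    "bresenham3d",
    "build_hyperplanes",
    "describe_patch",
    "describe_volume",
    "tile_volume",
    "N_BINS",
    "FUNCTION_ORDER",
]

N_BINS = 16
#: Per-family concatenation order of the five function histograms.
FUNCTION_ORDER = ("glob", "circ", "sqr", "ang", "rad")
ORIENTATIONS = ("yz", "xz", "xy")


@dataclass(frozen=True)
class VolumePatch:
    """A cubic sub-volume ``(side, side, z)`` with its corner coordinate."""

    values: np.ndarray
    origin: Tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError(f"patch must be 3D, got shape {v.shape}")
        if v.shape[0] != v.shape[1] or v.shape[0] % 2 == 0:
            raise ValueError(f"lateral sides must be odd and equal, got {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def depth(self) -> int:
        return self.values.shape[2]


@dataclass(frozen=True)
class CubicPatchDescriptor:
    """Descriptor of one cubic patch plus retained raw function values.

    ``vector`` is the concatenated histogram descriptor (240 for full 3D,
    80 for pseudo-3D).  ``raw_fG`` pools the projected global-function
    values over every plane of the patch; ``raw_fRA`` pools the radial and
    angular difference functions likewise.  Both feed the chromatin
    condensation ratios.
    """

    vector: np.ndarray
    raw_fG: np.ndarray
    raw_fRA: np.ndarray
    origin: Tuple[int, int, int] = (0, 0, 0)


@dataclass(frozen=True)
class VolumeDescriptorSet:
    """All cubic-patch descriptors of one volume plus run geometry."""

    descriptors: Tuple[CubicPatchDescriptor, ...]
    volume_shape: Tuple[int, int, int]
    patch_side: int
    depth: int
    stride: int
    mode: str
    bank_seed: int

    def __len__(self) -> int:
        return len(self.descriptors)

    def matrix(self) -> np.ndarray:
        """Stack descriptor vectors into an ``(n_patches, D)`` array."""
        if not self.descriptors:
            dim = 240 if self.mode == "3d" else 80
            return np.empty((0, dim))
        return np.stack([d.vector for d in self.descriptors])


# --------------------------------------------------------------------------
# 3D Bresenham
# --------------------------------------------------------------------------


def _bres_nonneg(d: np.ndarray) -> np.ndarray:
    """Integer Bresenham path from the origin for non-negative deltas.

    Driving axis is the largest delta (ties broken x > y > z).
    """
    dx, dy, dz = int(d[0]), int(d[1]), int(d[2])
    L = max(dx, dy, dz) + 1
    pts = np.zeros((L, 3), dtype=int)
    x = y = z = 0
    if dx >= dy and dx >= dz:
        p1, p2 = 2 * dy - dx, 2 * dz - dx
        for k in range(1, L):
            x += 1
            if p1 >= 0:
                y += 1
                p1 -= 2 * dx
            if p2 >= 0:
                z += 1
                p2 -= 2 * dx
            p1 += 2 * dy
            p2 += 2 * dz
            pts[k] = (x, y, z)
    elif dy >= dx and dy >= dz:
        p1, p2 = 2 * dx - dy, 2 * dz - dy
        for k in range(1, L):
            y += 1
            if p1 >= 0:
                x += 1
                p1 -= 2 * dy
            if p2 >= 0:
                z += 1
                p2 -= 2 * dy
            p1 += 2 * dx
            p2 += 2 * dz
            pts[k] = (x, y, z)
    else:
        p1, p2 = 2 * dx - dz, 2 * dy - dz
        for k in range(1, L):
            z += 1
            if p1 >= 0:
                x += 1
                p1 -= 2 * dz
            if p2 >= 0:
                y += 1
                p2 -= 2 * dz
            p1 += 2 * dx
            p2 += 2 * dy
            pts[k] = (x, y, z)
    return pts


def bresenham3d(p0: Sequence[int], p1: Sequence[int]) -> np.ndarray:
    """26-connected voxel line from ``p0`` to ``p1`` inclusive.

    Length equals the largest coordinate span plus one.  The path is
    canonicalized so that ``bresenham3d(b, a)`` is exactly the reverse of
    ``bresenham3d(a, b)``, and reflecting an axis reflects the path.
    """
    a = np.asarray(p0, dtype=int)
    b = np.asarray(p1, dtype=int)
    if tuple(b) < tuple(a):
        return bresenham3d(b, a)[::-1]
    d = b - a
    s = np.sign(d)
    base = _bres_nonneg(np.abs(d))
    return a + s * base


def _line5(p0: Sequence[int], p1: Sequence[int]) -> np.ndarray:
    """Exactly five voxels along the line from ``p0`` to ``p1``.

    Paths longer than 5 are subsampled at evenly spaced, reversal-symmetric
    indices; shorter paths are densified by rounding the parametric line at
    five evenly spaced fractions (mirrored so the sample set is symmetric
    under endpoint exchange).
    """
    path = bresenham3d(p0, p1)
    L = len(path)
    if L == 5:
        return path
    if L > 5:
        idx = np.empty(5, dtype=int)
        idx[0] = 0
        idx[1] = int(np.floor((L - 1) / 4.0 + 0.5))
        idx[2] = (L - 1) // 2
        idx[3] = L - 1 - idx[1]
        idx[4] = L - 1
        return path[idx]
    a = np.asarray(p0, dtype=float)
    b = np.asarray(p1, dtype=float)
    pts = np.empty((5, 3), dtype=int)
    for k in range(2):
        t = k / 4.0
        pts[k] = np.floor(a + t * (b - a) + 0.5).astype(int)
        pts[4 - k] = (a + b).astype(int) - pts[k]
    pts[2] = np.floor((a + b) / 2.0 + 0.5).astype(int)
    return pts


# --------------------------------------------------------------------------
# Hyperplane construction
# --------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _plane_tables(depth: int) -> dict:
    """Sampling index tables for all plane families of a 5x5x``depth`` patch.

    Returns arrays ``ix, iy, iz`` of shape ``(P, 5, 5)`` (P planes of 5x5
    samples) plus slices delimiting the yz / xz / xy families.
    """
    side = 5
    ix_list, iy_list, iz_list = [], [], []
    lateral = np.arange(side)
    # YZ family: one plane per (bottom column i, top column j); rows are the
    # 5 y positions, columns the 5 line samples.
    for i in range(side):
        for j in range(side):
            line = _line5((i, 0, 0), (j, 0, depth - 1))  # x,z vary; y free
            ix_list.append(np.broadcast_to(line[:, 0], (side, 5)))
            iy_list.append(np.broadcast_to(lateral[:, None], (side, 5)))
            iz_list.append(np.broadcast_to(line[:, 2], (side, 5)))
    # XZ family: rows are the 5 x positions, lines run over (y, z).
    for i in range(side):
        for j in range(side):
            line = _line5((0, i, 0), (0, j, depth - 1))
            ix_list.append(np.broadcast_to(lateral[:, None], (side, 5)))
            iy_list.append(np.broadcast_to(line[:, 1], (side, 5)))
            iz_list.append(np.broadcast_to(line[:, 2], (side, 5)))
    # XY family: the axial slices (resampled to 5 when deeper).
    if depth <= 5:
        z_idx = np.arange(depth)
    else:
        z_idx = np.round(np.linspace(0, depth - 1, 5)).astype(int)
    for z in z_idx:
        ix_list.append(np.broadcast_to(lateral[:, None], (side, side)))
        iy_list.append(np.broadcast_to(lateral, (side, side)))
        iz_list.append(np.full((side, side), z))
    n_xy = len(z_idx)
    return {
        "ix": np.array(ix_list),
        "iy": np.array(iy_list),
        "iz": np.array(iz_list),
        "slices": {
            "yz": slice(0, 25),
            "xz": slice(25, 50),
            "xy": slice(50, 50 + n_xy),
        },
        "n_planes": 50 + n_xy,
    }


def build_hyperplanes(patch: VolumePatch, orientation: str) -> List[np.ndarray]:
    """All 5x5 sampling planes of one family (``'yz'``, ``'xz'`` or ``'xy'``)."""
    if not isinstance(patch, VolumePatch):
        patch = VolumePatch(np.asarray(patch))
    if patch.side != 5:
        raise ValueError(f"only lateral side 5 is supported, got {patch.side}")
    orientation = orientation.lower()
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    tab = _plane_tables(patch.depth)
    sl = tab["slices"][orientation]
    planes = patch.values[tab["ix"][sl], tab["iy"][sl], tab["iz"][sl]]
    return [planes[k] for k in range(planes.shape[0])]


# --------------------------------------------------------------------------
# Descriptor computation
# --------------------------------------------------------------------------


def _hist16_rows(vals: np.ndarray) -> np.ndarray:
    """Row-wise 16-bin equal-width L1-normalized histograms.

    Bin edges span each row's own [min, max]; a degenerate (constant) row
    puts all mass in the first bin.
    """
    vals = np.asarray(vals, dtype=float)
    N, m = vals.shape
    lo = vals.min(axis=1, keepdims=True)
    hi = vals.max(axis=1, keepdims=True)
    span = hi - lo
    degen = span[:, 0] == 0
    safe_span = np.where(span == 0, 1.0, span)
    b = np.floor((vals - lo) / safe_span * N_BINS).astype(int)
    np.clip(b, 0, N_BINS - 1, out=b)
    rows = np.repeat(np.arange(N), m)
    counts = np.bincount(rows * N_BINS + b.ravel(), minlength=N * N_BINS)
    hist = counts.reshape(N, N_BINS).astype(float) / m
    if degen.any():
        hist[degen] = 0.0
        hist[degen, 0] = 1.0
    return hist


def _describe_batch(
    patches: np.ndarray, bank: RPBank, mode: str
) -> Tuple[np.ndarray, List[np.ndarray], List[np.ndarray]]:
    """Descriptor vectors and raw pooled function values for many patches.

    ``patches`` has shape ``(Np, 5, 5, depth)``.
    """
    Np = patches.shape[0]
    depth = patches.shape[3]
    tab = _plane_tables(depth)
    if mode == "3d":
        families = ["yz", "xz", "xy"]
        sel = np.arange(tab["n_planes"])
    elif mode == "pseudo3d":
        families = ["xy"]
        sel = np.arange(tab["slices"]["xy"].start, tab["slices"]["xy"].stop)
    else:
        raise ValueError(f"mode must be '3d' or 'pseudo3d', got {mode!r}")
    ix, iy, iz = tab["ix"][sel], tab["iy"][sel], tab["iz"][sel]
    P = len(sel)
    planes = patches[:, ix, iy, iz].reshape(Np * P, 5, 5)
    pats = extract_pattern_matrix(planes)
    a = bank.a
    funcs = {
        name: (pats[name] @ bank[name].T).reshape(Np, P, a)
        for name in PATTERN_NAMES
    }
    # family offsets within the selected planes
    fam_slices = {}
    off = 0
    for fam in families:
        width = tab["slices"][fam].stop - tab["slices"][fam].start
        fam_slices[fam] = slice(off, off + width)
        off += width
    blocks = []
    for fam in families:
        fsl = fam_slices[fam]
        for name in FUNCTION_ORDER:
            pooled = funcs[name][:, fsl, :].reshape(Np, -1)
            blocks.append(_hist16_rows(pooled))
    vectors = np.concatenate(blocks, axis=1)
    raw_fG = [funcs["glob"][i].ravel() for i in range(Np)]
    raw_fRA = [
        np.concatenate([funcs["rad"][i].ravel(), funcs["ang"][i].ravel()])
        for i in range(Np)
    ]
    return vectors, raw_fG, raw_fRA


def describe_patch(patch: VolumePatch, bank: RPBank, mode: str = "3d") -> CubicPatchDescriptor:
    """Compute the histogram descriptor of one cubic patch.

    Full 3D mode pools the YZ, XZ and XY plane families (240-dim vector);
    pseudo-3D keeps the XY family only (80-dim).
    """
    if not isinstance(patch, VolumePatch):
        patch = VolumePatch(np.asarray(patch))
    if patch.side != 5:
        raise ValueError(f"only lateral side 5 is supported, got {patch.side}")
    if bank.n != 2:
        raise ValueError("bank must be built for n=2 (5x5 planes)")
    vec, raw_g, raw_ra = _describe_batch(patch.values[None], bank, mode)
    return CubicPatchDescriptor(
        vector=vec[0], raw_fG=raw_g[0], raw_fRA=raw_ra[0], origin=patch.origin
    )


def tile_volume(
    volume: np.ndarray,
    patch_side: int = 5,
    depth: int = 5,
    stride: int | None = None,
) -> List[VolumePatch]:
    """Non-overlapping cubic tiling of a volume; border remainders dropped.

    ``depth`` is clamped to the volume's z extent.  A volume smaller than
    one patch laterally yields an empty list with a warning.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"volume must be 3D, got shape {volume.shape}")
    if stride is None:
        stride = patch_side
    X, Y, Z = volume.shape
    d = min(depth, Z)
    if X < patch_side or Y < patch_side:
        warnings.warn(
            f"volume {volume.shape} smaller than one {patch_side}x{patch_side} patch",
            stacklevel=2,
        )
        return []
    patches = []
    for z0 in range(0, Z - d + 1, d):
        for x0 in range(0, X - patch_side + 1, stride):
            for y0 in range(0, Y - patch_side + 1, stride):
                patches.append(
                    VolumePatch(
                        values=volume[
                            x0 : x0 + patch_side, y0 : y0 + patch_side, z0 : z0 + d
                        ],
                        origin=(x0, y0, z0),
                    )
                )
    return patches


def describe_volume(
    volume: np.ndarray,
    bank: RPBank,
    mode: str = "3d",
    patch_side: int = 5,
    depth: int = 5,
    stride: int | None = None,
) -> VolumeDescriptorSet:
    """Tile a volume and describe every cubic patch.

    Deterministic for fixed ``(volume, bank, parameters)``.
    """
    volume = np.asarray(volume, dtype=float)
    patches = tile_volume(volume, patch_side=patch_side, depth=depth, stride=stride)
    if stride is None:
        stride = patch_side
    d = min(depth, volume.shape[2]) if volume.ndim == 3 else depth
    if not patches:
        return VolumeDescriptorSet(
            descriptors=(),
            volume_shape=tuple(volume.shape),
            patch_side=patch_side,
            depth=d,
            stride=stride,
            mode=mode,
            bank_seed=bank.seed,
        )
    stack = np.stack([p.values for p in patches])
    vectors, raw_g, raw_ra = _describe_batch(stack, bank, mode)
    descs = tuple(
        CubicPatchDescriptor(
            vector=vectors[i], raw_fG=raw_g[i], raw_fRA=raw_ra[i], origin=patches[i].origin
        )
        for i in range(len(patches))
    )
    return VolumeDescriptorSet(
        descriptors=descs,
        volume_shape=tuple(volume.shape),
        patch_side=patch_side,
        depth=d,
        stride=stride,
        mode=mode,
        bank_seed=bank.seed,
    )
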