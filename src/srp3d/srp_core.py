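"""Sorted-pattern extraction and random-projection compression for square patches.

A square ``(2n+1) x (2n+1)`` patch is summarised by five sorted vectors --
global, square-ring, circular-ring intensities, and angular / radial
intensity differences -- each compressed to ``10*(n-1)`` dimensions by a
fixed ``{+1,-1}`` random-projection matrix shared across all patches of a
run.  Sorting within rings makes the intensity patterns invariant to patch
rotation; the difference patterns encode local gradient structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "PATTERN_NAMES",
    "SquarePatch",
    "PatternVectors",
    "RPBank",
    "SRPFunctions",
    "rp_output_dim",
    "extract_patterns",
    "extract_pattern_matrix",
    "make_rp_bank",
    "project",
    "pattern_lengths",
]

#: Canonical pattern order used throughout the package.
PATTERN_NAMES = ("glob", "sqr", "circ", "ang", "rad")


def rp_output_dim(n: int) -> int:
    """Output dimension ``a`` of the random projection for ring parameter ``n``.

    ``a`` is 10 at ``n=2`` and grows by 10 with every unit increase of ``n``.
    """
    if n < 2:
        raise ValueError(f"ring parameter n must be >= 2, got {n}")
    return 10 * (int(n) - 1)


def pattern_lengths(n: int) -> Dict[str, int]:
    """Lengths ``b_f`` of the five pattern vectors for ring parameter ``n``."""
    if n < 2:
        raise ValueError(f"ring parameter n must be >= 2, got {n}")
    side = 2 * n + 1
    n_ring = 4 * n * (n + 1)  # sum of 8r over r=1..n
    return {
        "glob": side * side,
        "sqr": side * side,
        "circ": 1 + n_ring,
        "ang": n_ring,
        "rad": n_ring,
    }


@dataclass(frozen=True)
class SquarePatch:
    """A square odd-sided intensity patch with ``n`` concentric rings."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"patch must be square 2D, got shape {v.shape}")
        if v.shape[0] % 2 == 0 or v.shape[0] < 5:
            raise ValueError(f"patch side must be odd and >= 5, got {v.shape[0]}")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("patch intensities must be finite and non-negative")
        object.__setattr__(self, "values", v)

    @property
    def side(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        """Ring-count parameter: side = 2n+1."""
        return (self.side - 1) // 2


@dataclass(frozen=True)
class PatternVectors:
    """The five sorted pattern vectors of one patch.

    ``glob``: all pixels sorted. ``sqr``: center pixel, then each square
    (Chebyshev) ring sorted, innermost first. ``circ``: center, then each
    circular ring's interpolated samples sorted. ``ang``: per ring, sorted
    differences between consecutive circular samples (with wrap).
    ``rad``: per ring, sorted differences between a ring sample and the
    same-angle sample one radius inward (ring 1 against the center).
    """

    glob: np.ndarray
    sqr: np.ndarray
    circ: np.ndarray
    ang: np.ndarray
    rad: np.ndarray

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in PATTERN_NAMES}


@dataclass(frozen=True)
class RPBank:
    """Five fixed ``{+1,-1}`` projection matrices, one per pattern.

    Drawn once from a seeded RNG and reused for every patch of a run so
    that projected descriptors are mutually comparable.
    """

    matrices: Mapping[str, np.ndarray]
    n: int
    a: int
    seed: int

    def __post_init__(self) -> None:
        lengths = pattern_lengths(self.n)
        for name in PATTERN_NAMES:
            m = self.matrices[name]
            if m.shape != (self.a, lengths[name]):
                raise ValueError(
                    f"matrix {name!r} has shape {m.shape}, "
                    f"expected {(self.a, lengths[name])}"
                )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.matrices[name]


@dataclass(frozen=True)
class SRPFunctions:
    """Projected function values of one patch (each of length ``a``)."""

    f_G: np.ndarray
    f_S: np.ndarray
    f_C: np.ndarray
    f_A: np.ndarray
    f_R: np.ndarray


# --------------------------------------------------------------------------
# Ring geometry
#
# Circular samples are taken at 8r equally spaced angles on ring r.  Only
# the 2r first-quadrant offsets are computed from trigonometry; the other
# three quadrants reuse those offsets through exact 90-degree index
# permutations of the patch.  Bilinear weights are therefore identical
# across quadrants and rotating a patch by a multiple of 90 degrees permutes
# the sample values bit-exactly.
# --------------------------------------------------------------------------


def _rot90_flat_perm(side: int) -> np.ndarray:
    """perm with ``np.rot90(P).flat[i] == P.flat[perm[i]]``."""
    idx = np.arange(side * side).reshape(side, side)
    return np.rot90(idx, 1).ravel()


def _bilinear_tables(side: int, radius: float, angles: np.ndarray):
    """Neighbor flat-index and weight tables for first-quadrant samples.

    Returns ``(idx, w)`` of shape ``(len(angles), 4)`` such that the sample
    value is ``sum(w * patch.flat[idx])`` evaluated in fixed order.
    """
    c = (side - 1) / 2.0
    rows = c + radius * np.sin(angles)
    cols = c + radius * np.cos(angles)
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr = rows - r0
    fc = cols - c0
    r0 = np.clip(r0, 0, side - 1)
    c0 = np.clip(c0, 0, side - 1)
    r1 = np.clip(r0 + 1, 0, side - 1)
    c1 = np.clip(c0 + 1, 0, side - 1)
    idx = np.stack(
        [r0 * side + c0, r0 * side + c1, r1 * side + c0, r1 * side + c1], axis=1
    )
    w = np.stack(
        [(1 - fr) * (1 - fc), (1 - fr) * fc, fr * (1 - fc), fr * fc], axis=1
    )
    return idx, w


@dataclass(frozen=True)
class _RingGeometry:
    """Precomputed index/weight tables for one patch size."""

    n: int
    side: int
    center_flat: int
    sqr_ring_idx: tuple  # per ring: sorted-later flat indices (8r,)
    circ_idx: tuple  # per ring: (8r, 4) neighbor indices
    circ_w: tuple  # per ring: (8r, 4) weights
    inner_idx: tuple  # per ring: (8r, 4) indices at radius r-1, same angles
    inner_w: tuple


def _quadrant_tables(side: int, radius: float, n_base: int, base_angles: np.ndarray):
    """Full-circle tables built from first-quadrant ones via rot90 permutations."""
    perm = _rot90_flat_perm(side)
    idx_q, w_q = _bilinear_tables(side, radius, base_angles)
    idx_all = [idx_q]
    cur = idx_q
    for _ in range(3):
        cur = perm[cur]
        idx_all.append(cur)
    idx = np.concatenate(idx_all, axis=0)
    w = np.concatenate([w_q] * 4, axis=0)
    return idx, w


@lru_cache(maxsize=None)
def _ring_geometry(n: int) -> _RingGeometry:
    side = 2 * n + 1
    c = n
    ii, jj = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    cheb = np.maximum(np.abs(ii - c), np.abs(jj - c))
    sqr_ring_idx = []
    circ_idx, circ_w, inner_idx, inner_w = [], [], [], []
    for r in range(1, n + 1):
        sqr_ring_idx.append(np.flatnonzero(cheb.ravel() == r))
        base_angles = 2.0 * np.pi * np.arange(2 * r) / (8 * r)
        ci, cw = _quadrant_tables(side, float(r), 2 * r, base_angles)
        circ_idx.append(ci)
        circ_w.append(cw)
        ri, rw = _quadrant_tables(side, float(r - 1), 2 * r, base_angles)
        inner_idx.append(ri)
        inner_w.append(rw)
    return _RingGeometry(
        n=n,
        side=side,
        center_flat=c * side + c,
        sqr_ring_idx=tuple(sqr_ring_idx),
        circ_idx=tuple(circ_idx),
        circ_w=tuple(circ_w),
        inner_idx=tuple(inner_idx),
        inner_w=tuple(inner_w),
    )


def _sample(flat: np.ndarray, idx: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Bilinear samples for a batch: ``flat`` is (B, side*side)."""
    # fixed summation order keeps 90-degree rotations bit-exact
    return (
        flat[:, idx[:, 0]] * w[:, 0]
        + flat[:, idx[:, 1]] * w[:, 1]
        + flat[:, idx[:, 2]] * w[:, 2]
        + flat[:, idx[:, 3]] * w[:, 3]
    )


def extract_pattern_matrix(patches: np.ndarray) -> Dict[str, np.ndarray]:
    """Vectorized pattern extraction for a batch of square patches.

    Parameters
    ----------
    patches:
        Array of shape ``(B, side, side)`` with odd ``side >= 5``.

    Returns
    -------
    dict mapping pattern name to a ``(B, b_f)`` array.
    """
    patches = np.asarray(patches, dtype=float)
    if patches.ndim != 3 or patches.shape[1] != patches.shape[2]:
        raise ValueError(f"expected (B, side, side), got {patches.shape}")
    side = patches.shape[1]
    if side % 2 == 0 or side < 5:
        raise ValueError(f"patch side must be odd and >= 5, got {side}")
    n = (side - 1) // 2
    geo = _ring_geometry(n)
    B = patches.shape[0]
    flat = patches.reshape(B, side * side)

    glob = np.sort(flat, axis=1)

    center = flat[:, geo.center_flat : geo.center_flat + 1]
    sqr_parts = [center]
    circ_parts = [center]
    ang_parts = []
    rad_parts = []
    for r in range(n):
        sqr_parts.append(np.sort(flat[:, geo.sqr_ring_idx[r]], axis=1))
        ring = _sample(flat, geo.circ_idx[r], geo.circ_w[r])
        circ_parts.append(np.sort(ring, axis=1))
        ang_parts.append(np.sort(ring - np.roll(ring, -1, axis=1), axis=1))
        inner = _sample(flat, geo.inner_idx[r], geo.inner_w[r])
        rad_parts.append(np.sort(ring - inner, axis=1))

    return {
        "glob": glob,
        "sqr": np.concatenate(sqr_parts, axis=1),
        "circ": np.concatenate(circ_parts, axis=1),
        "ang": np.concatenate(ang_parts, axis=1),
        "rad": np.concatenate(rad_parts, axis=1),
    }


def extract_patterns(patch: SquarePatch | np.ndarray) -> PatternVectors:
    """Extract the five sorted pattern vectors from one square patch."""
    if not isinstance(patch, SquarePatch):
        patch = SquarePatch(np.asarray(patch))
    mats = extract_pattern_matrix(patch.values[None])
    return PatternVectors(**{k: v[0] for k, v in mats.items()})


def make_rp_bank(n: int, seed: int = 42) -> RPBank:
    """Draw the five ``{+1,-1}`` projection matrices from a seeded RNG.

    Matrices are drawn in the fixed order glob, sqr, circ, ang, rad so a
    given ``(n, seed)`` always yields a bit-identical bank.
    """
    a = rp_output_dim(n)
    lengths = pattern_lengths(n)
    rng = np.random.default_rng(seed)
    matrices = {}
    for name in PATTERN_NAMES:
        m = rng.integers(0, 2, size=(a, lengths[name])).astype(float) * 2.0 - 1.0
        m.setflags(write=False)
        matrices[name] = m
    return RPBank(matrices=matrices, n=n, a=a, seed=seed)


def project(patterns: PatternVectors, bank: RPBank) -> SRPFunctions:
    """Compress each pattern vector with its projection matrix: ``f = RP @ x``."""
    out = {}
    for name in PATTERN_NAMES:
        x = np.asarray(getattr(patterns, name), dtype=float)
        m = bank[name]
        if x.shape[0] != m.shape[1]:
            raise ValueError(
                f"pattern {name!r} has length {x.shape[0]}, "
                f"bank expects {m.shape[1]}"
            )
        out[name] = m @ x
    return SRPFunctions(
        f_G=out["glob"], f_S=out["sqr"], f_C=out["circ"],
        f_A=out["ang"], f_R=out["rad"],
    )
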