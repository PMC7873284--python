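"""Synthetic DAPI-like nucleus phantoms with controllable chromatin condensation.

Each phantom is an ellipsoidal nucleus on a dark background: a smoothed
positive noise field models open (euchromatin-like) texture, and bright
spherical foci with Gaussian-feathered edges model condensed chromatin.
Focus count, radius and intensity gain are the condensation dials, so
cohorts with known separability can be generated for end-to-end testing.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "PhantomVolume",
    "generate_nucleus",
    "generate_cohorts",
    "make_cohorts",
    "condensed_preset",
    "open_preset",
]


@dataclass(frozen=True)
class PhantomParams:
    """Generator knobs for one phantom nucleus."""

    shape: Tuple[int, int, int] = (64, 64, 15)
    semi_axes: Tuple[float, float, float] = (26.0, 22.0, 6.0)
    background: float = 0.0
    base_level: float = 100.0
    base_smooth_sigma: float = 2.0
    focus_count: int = 10
    focus_radius: float = 2.0
    focus_gain: float = 3.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for ax, ext in zip(self.semi_axes, self.shape):
            if 2 * ax > ext:
                raise ValueError(
                    f"semi-axis {ax} does not fit in volume extent {ext}"
                )
        if self.focus_gain < 1:
            raise ValueError("focus gain must be >= 1")
        if min(self.background, self.base_level, self.noise_sd) < 0:
            raise ValueError("levels must be non-negative")


@dataclass(frozen=True)
class PhantomVolume:
    """A generated phantom: intensities, nucleus mask, class label, params."""

    values: np.ndarray
    mask: np.ndarray
    label: str
    params: PhantomParams


def condensed_preset(**overrides) -> PhantomParams:
    """High-condensation preset: many bright, sharp foci."""
    base = PhantomParams(focus_count=24, focus_radius=4.0, focus_gain=4.0)
    return replace(base, **overrides)


def open_preset(**overrides) -> PhantomParams:
    """Open-chromatin preset: few dim foci."""
    base = PhantomParams(focus_count=3, focus_radius=2.0, focus_gain=1.3)
    return replace(base, **overrides)


def _ellipsoid_mask(shape, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    c = [(s - 1) / 2.0 for s in shape]
    q = sum(((g - ci) / ai) ** 2 for g, ci, ai in zip(grids, c, semi_axes))
    return q <= 1.0


def generate_nucleus(params: PhantomParams, label: str = "") -> PhantomVolume:
    """Generate one phantom nucleus, deterministic for a fixed seed.

    Intensities are rounded to whole numbers so written 16-bit files match
    the in-memory array exactly.  Outside the ellipsoid mask the volume is
    exactly the background level.  With ``focus_gain == 1`` the foci are a
    no-op and the volume equals the focus-free texture.
    """
    rng = np.random.default_rng(params.seed)
    mask = _ellipsoid_mask(params.shape, params.semi_axes)

    base_noise = rng.uniform(0.5, 1.5, size=params.shape)
    base = ndimage.gaussian_filter(base_noise, sigma=params.base_smooth_sigma)
    texture = params.base_level * base
    # drawn before foci so the noise field is independent of focus_count
    noise = rng.normal(0.0, params.noise_sd, size=params.shape)

    # focus centers inside the mask eroded by one voxel
    core = ndimage.binary_erosion(mask)
    candidates = np.argwhere(core if core.any() else mask)
    if candidates.size == 0:
        raise ValueError("mask too small to place foci")
    gain_field = np.ones(params.shape)
    if params.focus_count > 0 and params.focus_gain > 0:
        feather = np.zeros(params.shape)
        placed = 0
        for _ in range(100 * params.focus_count):
            if placed == params.focus_count:
                break
            c = candidates[rng.integers(len(candidates))]
            placed += 1
            grids = np.ogrid[tuple(slice(0, s) for s in params.shape)]
            d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
            sphere = (d2 <= params.focus_radius**2).astype(float)
            soft = ndimage.gaussian_filter(sphere, sigma=1.0)
            peak = soft.max()
            if peak > 0:
                np.maximum(feather, soft / peak, out=feather)
        if placed < params.focus_count:
            raise ValueError("could not place all foci inside the mask")
        gain_field = 1.0 + (params.focus_gain - 1.0) * np.clip(feather, 0.0, 1.0)

    values = np.full(params.shape, float(params.background))
    inside = np.clip(texture * gain_field + noise, 0.0, None)
    values[mask] = inside[mask]
    values = np.round(values)
    values[~mask] = params.background
    return PhantomVolume(values=values, mask=mask, label=label, params=params)


def generate_cohorts(
    n_per_class: int,
    condensed: Optional[PhantomParams] = None,
    open_: Optional[PhantomParams] = None,
    seed: int = 7,
) -> List[PhantomVolume]:
    """In-memory labelled cohorts: ``n_per_class`` condensed + open phantoms.

    Per-volume seeds are spawned deterministically from the master seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    condensed = condensed or condensed_preset()
    open_ = open_ or open_preset()
    seed_rng = np.random.default_rng(seed)
    child_seeds = seed_rng.integers(0, 2**31 - 1, size=2 * n_per_class)
    volumes = []
    for i in range(n_per_class):
        volumes.append(
            generate_nucleus(
                replace(condensed, seed=int(child_seeds[2 * i])), label="condensed"
            )
        )
        volumes.append(
            generate_nucleus(
                replace(open_, seed=int(child_seeds[2 * i + 1])), label="open"
            )
        )
    return volumes


def make_cohorts(
    out_dir: str | Path,
    n_per_class: int,
    condensed: Optional[PhantomParams] = None,
    open_: Optional[PhantomParams] = None,
    seed: int = 7,
) -> List[Path]:
    """Write labelled cohorts to disk as 16-bit multi-page TIFFs.

    Produces ``2 * n_per_class`` TIFF files, a ``labels.csv`` (filename,
    class, seed) and a ``params.json`` with both presets.
    """
    from srp3d.io import write_volume

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    condensed = condensed or condensed_preset()
    open_ = open_ or open_preset()
    volumes = generate_cohorts(n_per_class, condensed, open_, seed=seed)
    paths = []
    rows = []
    for i, vol in enumerate(volumes):
        path = out_dir / f"phantom_{i:04d}_{vol.label}.tif"
        write_volume(path, vol.values.astype(np.uint16))
        paths.append(path)
        rows.append((path.name, vol.label, vol.params.seed))
    with open(out_dir / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "class", "seed"])
        writer.writerows(rows)
    with open(out_dir / "params.json", "w") as fh:
        json.dump(
            {
                "master_seed": seed,
                "n_per_class": n_per_class,
                "condensed": asdict(condensed),
                "open": asdict(open_),
            },
            fh,
            indent=2,
        )
    return paths
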