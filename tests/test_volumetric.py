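import numpy as np
import pytest

from srp3d.srp_core import PATTERN_NAMES, extract_pattern_matrix, make_rp_bank
from srp3d.volumetric import (
    VolumePatch,
    bresenham3d,
    build_hyperplanes,
    describe_patch,
    describe_volume,
    tile_volume,
    _plane_tables,
)


# ---------------------------------------------------------------------------
# bresenham3d
# ---------------------------------------------------------------------------


def test_bresenham_axis_aligned():
    path = bresenham3d((0, 0, 0), (0, 0, 4))
    assert path.tolist() == [[0, 0, 0], [0, 0, 1], [0, 0, 2], [0, 0, 3], [0, 0, 4]]


def test_bresenham_main_diagonal():
    path = bresenham3d((0, 0, 0), (4, 4, 4))
    assert path.tolist() == [[k, k, k] for k in range(5)]


def test_bresenham_matches_parametric_rounding_oracle():
    # oracle: round-half-up of the parametric line at the driving-axis steps
    p0, p1 = np.array([0, 0, 0]), np.array([4, 1, 2])
    L = 5
    oracle = np.floor(
        p0 + np.linspace(0, 1, L)[:, None] * (p1 - p0) + 0.5
    ).astype(int)
    assert np.array_equal(bresenham3d(p0, p1), oracle)


def test_bresenham_length_and_endpoints(rng):
    for _ in range(100):
        p0 = rng.integers(-6, 7, 3)
        p1 = rng.integers(-6, 7, 3)
        path = bresenham3d(p0, p1)
        assert len(path) == np.abs(p1 - p0).max() + 1
        assert np.array_equal(path[0], p0) and np.array_equal(path[-1], p1)
        steps = np.abs(np.diff(path, axis=0))
        assert steps.max(initial=0) <= 1  # 26-connected
        # every voxel within half a step of the continuous line
        t = np.linspace(0, 1, len(path))[:, None]
        assert np.abs(path - (p0 + t * (p1 - p0))).max() <= 0.5 + 1e-9


def test_bresenham_reversal_symmetry(rng):
    for _ in range(50):
        p0 = rng.integers(-5, 6, 3)
        p1 = rng.integers(-5, 6, 3)
        assert np.array_equal(bresenham3d(p1, p0), bresenham3d(p0, p1)[::-1])


# ---------------------------------------------------------------------------
# build_hyperplanes
# ---------------------------------------------------------------------------


def test_hyperplane_counts_5x5x5(rng):
    patch = VolumePatch(rng.uniform(0, 9, (5, 5, 5)))
    yz = build_hyperplanes(patch, "yz")
    xz = build_hyperplanes(patch, "xz")
    xy = build_hyperplanes(patch, "xy")
    assert len(yz) == 25 and len(xz) == 25 and len(xy) == 5
    for plane in yz + xz + xy:
        assert plane.shape == (5, 5)


def test_hyperplane_total_count(rng):
    patch = VolumePatch(rng.uniform(0, 9, (5, 5, 5)))
    total = sum(len(build_hyperplanes(patch, o)) for o in ("yz", "xz", "xy"))
    assert total == 55


def test_hyperplanes_constant_patch():
    patch = VolumePatch(np.full((5, 5, 5), 3.0))
    for orientation in ("yz", "xz", "xy"):
        for plane in build_hyperplanes(patch, orientation):
            assert np.all(plane == 3.0)


def test_hyperplanes_vertical_pairing_is_column():
    # plane (i, i) of the YZ family is the vertical slice x=i
    vol = np.arange(125.0).reshape(5, 5, 5)
    patch = VolumePatch(vol)
    planes = build_hyperplanes(patch, "yz")
    for i in range(5):
        assert np.array_equal(planes[i * 5 + i], vol[i, :, :])


def test_hyperplanes_reject_wrong_side(rng):
    with pytest.raises(ValueError):
        build_hyperplanes(VolumePatch(rng.uniform(0, 1, (7, 7, 5))), "yz")


def test_hyperplanes_shallow_stack(rng):
    patch = VolumePatch(rng.uniform(0, 9, (5, 5, 3)))
    planes = build_hyperplanes(patch, "xy")
    assert len(planes) == 3
    assert len(build_hyperplanes(patch, "yz")) == 25


# ---------------------------------------------------------------------------
# describe_patch
# ---------------------------------------------------------------------------


def test_descriptor_length_240(bank, rng):
    patch = VolumePatch(rng.uniform(0, 255, (5, 5, 5)))
    d = describe_patch(patch, bank)
    assert d.vector.shape == (240,)
    assert d.raw_fG.shape == (55 * 10,)
    assert d.raw_fRA.shape == (55 * 2 * 10,)


def test_descriptor_single_orientation_length_80(bank, rng):
    patch = VolumePatch(rng.uniform(0, 255, (5, 5, 5)))
    d = describe_patch(patch, bank, mode="pseudo3d")
    assert d.vector.shape == (80,)


def test_histogram_blocks_sum_to_one(bank, rng):
    patch = VolumePatch(rng.uniform(0, 255, (5, 5, 5)))
    d = describe_patch(patch, bank)
    blocks = d.vector.reshape(15, 16)
    assert np.allclose(blocks.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(d.vector >= 0)


def test_constant_patch_degenerate_difference_bins(bank):
    # constant patch: every difference projection is 0, so the ang/rad blocks
    # collapse to the degenerate single-bin case.  The intensity functions of
    # a constant plane are c * rowsums(RP) -- ten distinct values -- so their
    # blocks are non-degenerate but identical across the three families
    # (every plane of a constant patch is the same).
    d = describe_patch(VolumePatch(np.full((5, 5, 5), 4.0)), bank)
    blocks = d.vector.reshape(3, 5, 16)
    for family in range(3):
        for func in (3, 4):  # ang, rad
            assert blocks[family, func, 0] == 1.0
            assert np.all(blocks[family, func, 1:] == 0.0)
    for func in range(5):
        assert np.array_equal(blocks[0, func], blocks[1, func])
        assert np.array_equal(blocks[0, func], blocks[2, func])


def test_describe_patch_requires_n2_bank(rng):
    bank3 = make_rp_bank(3, seed=0)
    with pytest.raises(ValueError):
        describe_patch(VolumePatch(rng.uniform(0, 1, (5, 5, 5))), bank3)


# ---------------------------------------------------------------------------
# tile_volume
# ---------------------------------------------------------------------------


def test_tiling_64x64x15(rng):
    vol = rng.uniform(0, 1, (64, 64, 15))
    patches = tile_volume(vol, 5, 5, 5)
    assert len(patches) == 12 * 12 * 3


def test_tiling_single_patch(rng):
    assert len(tile_volume(rng.uniform(0, 1, (5, 5, 5)))) == 1


def test_tiling_depth_clamps(rng):
    vol = rng.uniform(0, 1, (64, 64, 4))
    patches = tile_volume(vol, 5, 5, 5)
    assert len(patches) == 12 * 12
    assert patches[0].depth == 4
    # XY family then uses 4 slices
    assert len(build_hyperplanes(patches[0], "xy")) == 4


def test_tiling_small_volume_warns(rng):
    with pytest.warns(UserWarning):
        patches = tile_volume(rng.uniform(0, 1, (3, 3, 5)))
    assert patches == []


def test_tiling_origins_cover_grid(rng):
    vol = rng.uniform(0, 1, (11, 16, 5))
    patches = tile_volume(vol, 5, 5, 5)
    origins = {p.origin for p in patches}
    assert origins == {(x, y, 0) for x in (0, 5) for y in (0, 5, 10)}


# ---------------------------------------------------------------------------
# describe_volume
# ---------------------------------------------------------------------------


def test_describe_volume_3d(bank, random_volume):
    dset = describe_volume(random_volume, bank, mode="3d")
    assert len(dset) == 4
    assert dset.matrix().shape == (4, 240)


def test_describe_volume_pseudo3d(bank, random_volume):
    dset = describe_volume(random_volume, bank, mode="pseudo3d")
    assert len(dset) == 4
    assert dset.matrix().shape == (4, 80)


def test_describe_volume_deterministic(random_volume):
    b1 = make_rp_bank(2, seed=11)
    b2 = make_rp_bank(2, seed=11)
    d1 = describe_volume(random_volume, b1)
    d2 = describe_volume(random_volume, b2)
    assert np.array_equal(d1.matrix(), d2.matrix())
    for a, b in zip(d1.descriptors, d2.descriptors):
        assert np.array_equal(a.raw_fG, b.raw_fG)
        assert np.array_equal(a.raw_fRA, b.raw_fRA)


def test_describe_volume_matches_describe_patch(bank, random_volume):
    dset = describe_volume(random_volume, bank)
    for patch, desc in zip(tile_volume(random_volume), dset.descriptors):
        single = describe_patch(patch, bank)
        assert np.array_equal(single.vector, desc.vector)
        assert np.array_equal(single.raw_fG, desc.raw_fG)


def test_bad_mode_rejected(bank, random_volume):
    with pytest.raises(ValueError):
        describe_volume(random_volume, bank, mode="2.5d")


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------


def _pooled_function_values(patch_values, bank):
    tab = _plane_tables(patch_values.shape[2])
    planes = patch_values[tab["ix"], tab["iy"], tab["iz"]]
    pats = extract_pattern_matrix(planes)
    return {name: pats[name] @ bank[name].T for name in PATTERN_NAMES}


@pytest.mark.parametrize("z", [5, 7])
def test_axial_flip_invariance(bank, rng, z):
    # reversing slice order permutes (bottom, top) pairings; the pooled value
    # multiset of the intensity patterns is unchanged bit-exactly and of the
    # circular/radial patterns up to float noise.  The signed angular
    # differences are chirality-sensitive and exempt (mirror negates them).
    vals = rng.uniform(0, 99, (5, 5, z))
    f0 = _pooled_function_values(vals, bank)
    f1 = _pooled_function_values(vals[:, :, ::-1].copy(), bank)
    for name in ("glob", "sqr"):
        assert np.array_equal(
            np.sort(f0[name].ravel()), np.sort(f1[name].ravel())
        )
    for name in ("circ", "rad"):
        assert np.allclose(
            np.sort(f0[name].ravel()), np.sort(f1[name].ravel()), atol=1e-9
        )


def test_axial_flip_exact_histogram_blocks(bank, rng):
    # the glob/sqr histogram blocks are bit-identical under slice reversal
    vals = rng.uniform(0, 99, (5, 5, 5))
    d0 = describe_patch(VolumePatch(vals), bank)
    d1 = describe_patch(VolumePatch(vals[:, :, ::-1].copy()), bank)
    blocks0 = d0.vector.reshape(3, 5, 16)
    blocks1 = d1.vector.reshape(3, 5, 16)
    # function order per family: glob, circ, sqr, ang, rad
    assert np.array_equal(blocks0[:, 0], blocks1[:, 0])  # glob
    assert np.array_equal(blocks0[:, 2], blocks1[:, 2])  # sqr


def test_sensitivity_smooth_vs_speckled(bank, rng):
    smooth = np.full((10, 10, 5), 50.0)
    speckled = 50.0 + 40.0 * (rng.uniform(size=(10, 10, 5)) > 0.8)
    d_smooth = describe_volume(smooth, bank).matrix()
    d_speck = describe_volume(speckled, bank).matrix()
    # difference-function blocks: ang (3) and rad (4) of each family
    idx = np.r_[48:80, 128:160, 208:240]
    assert np.linalg.norm(d_smooth[:, idx] - d_speck[:, idx]) > 0
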