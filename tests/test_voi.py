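"""VOI morphology against brute-force set computations on small grids."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import ndimage

from pulmopet.voi import (
    LOBE_NAMES,
    RV_NAME,
    VESSEL_NAMES,
    BinaryMask,
    GeometryError,
    VoiRecipe,
    build_vois,
    dilate,
    erode,
    hollow_shell,
    largest_connected_component,
    resample_mask,
    subtract,
)

CROSS = ndimage.generate_binary_structure(3, 1)


def cube_mask(n: int, pad: int = 2) -> BinaryMask:
    data = np.zeros((n + 2 * pad,) * 3, dtype=bool)
    data[pad : pad + n, pad : pad + n, pad : pad + n] = True
    return BinaryMask(data, (1.0, 1.0, 1.0), f"cube{n}")


def brute_erode(data: np.ndarray, iterations: int) -> np.ndarray:
    """Reference erosion: a voxel survives iff all 6 face neighbours are set."""
    out = data.copy()
    for _ in range(iterations):
        padded = np.pad(out, 1, constant_values=False)
        nxt = padded[1:-1, 1:-1, 1:-1].copy()
        for axis in range(3):
            for shift in (-1, 1):
                nxt &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
        out = nxt
    return out


class TestHollowShell:
    def test_7cube_depth3_keeps_all_but_centre(self):
        # 3 face-adjacency erosions of a 7-cube leave exactly the centre voxel
        shell = hollow_shell(cube_mask(7), depth=3)
        assert shell.n_voxels == 342

    def test_5cube_depth3_keeps_everything(self):
        shell = hollow_shell(cube_mask(5), depth=3)
        assert shell.n_voxels == 125

    def test_shell_is_subset_of_input(self):
        mask = cube_mask(9)
        shell = hollow_shell(mask, depth=3)
        assert not (shell.data & ~mask.data).any()

    def test_shell_and_core_partition_mask_exactly(self):
        mask = cube_mask(8)
        for depth in (1, 2, 3):
            shell = hollow_shell(mask, depth)
            core = erode(mask, depth)
            assert not (shell.data & core.data).any()
            assert ((shell.data | core.data) == mask.data).all()

    def test_depth_zero_rejected(self):
        with pytest.raises(ValueError):
            hollow_shell(cube_mask(5), depth=0)

    def test_empty_input_empty_output(self):
        empty = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert hollow_shell(empty, 3).n_voxels == 0


class TestDilateErode:
    def test_single_voxel_one_dilation_gives_cross(self):
        data = np.zeros((5, 5, 5), bool)
        data[2, 2, 2] = True
        out = dilate(BinaryMask(data, (1, 1, 1)), 1)
        assert out.n_voxels == 7

    def test_zero_iterations_is_identity(self):
        mask = cube_mask(3)
        assert (dilate(mask, 0).data == mask.data).all()

    @given(st.integers(0, 2**24 - 1), st.integers(1, 2))
    def test_dilation_extensive_and_duality(self, bits, iters):
        """Input subset of dilation; erosion = complement of dilation of
        the complement (checked on random small grids)."""
        data = np.zeros(24, dtype=bool)
        for i in range(24):
            data[i] = bool((bits >> i) & 1)
        data = data.reshape(2, 3, 4)
        # embed in padding so border effects match the unpadded complement
        data = np.pad(data, 3, constant_values=False)
        mask = BinaryMask(data, (1, 1, 1))
        dil = dilate(mask, iters)
        assert (mask.data <= dil.data).all()
        ero = erode(mask, iters)
        comp_dil = ndimage.binary_dilation(~data, structure=CROSS, iterations=iters)
        inner = (slice(iters, -iters),) * 3
        assert (ero.data[inner] == ~comp_dil[inner]).all()

    def test_erosion_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        data = rng.random((10, 10, 10)) < 0.6
        mask = BinaryMask(data, (1, 1, 1))
        for iters in (1, 2, 3):
            assert (erode(mask, iters).data == brute_erode(data, iters)).all()


class TestSubtract:
    def test_no_others_unchanged(self):
        mask = cube_mask(4)
        assert (subtract(mask, []).data == mask.data).all()

    def test_covering_others_empty(self):
        mask = cube_mask(4)
        assert subtract(mask, [mask]).n_voxels == 0

    def test_disjoint_others_unchanged(self):
        mask = cube_mask(3, pad=3)
        other = BinaryMask(np.zeros_like(mask.data), mask.voxel_size_mm)
        other.data[0, 0, 0] = True
        assert (subtract(mask, [other]).data == mask.data).all()

    def test_grid_mismatch_rejected(self):
        a = cube_mask(3)
        b = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        with pytest.raises(GeometryError):
            subtract(a, [b])

    def test_idempotent(self):
        mask = cube_mask(6)
        others = [dilate(cube_mask(2, pad=4), 1)]
        once = subtract(mask, others)
        twice = subtract(once, others)
        assert (once.data == twice.data).all()


class TestLargestConnectedComponent:
    def test_keeps_biggest_blob(self):
        data = np.zeros((10, 10, 10), bool)
        data[1:3, 1:6, 1] = True     # 10 voxels
        data[7:8, 7:10, 7] = True    # 3 voxels
        out = largest_connected_component(BinaryMask(data, (1, 1, 1)))
        assert out.n_voxels == 10
        assert out.data[1, 1, 1] and not out.data[7, 7, 7]

    def test_single_blob_unchanged(self):
        mask = cube_mask(3)
        assert (largest_connected_component(mask).data == mask.data).all()

    def test_tie_broken_by_lowest_linear_index(self):
        data = np.zeros((8, 8, 8), bool)
        data[6, 6, 6] = True
        data[1, 1, 1] = True
        out = largest_connected_component(BinaryMask(data, (1, 1, 1)))
        assert out.data[1, 1, 1] and not out.data[6, 6, 6]

    def test_matches_bruteforce_on_random_grid(self):
        rng = np.random.default_rng(11)
        data = rng.random((16, 16, 16)) < 0.3
        out = largest_connected_component(BinaryMask(data, (1, 1, 1)))
        labels, n = ndimage.label(data, structure=np.ones((3, 3, 3), bool))
        sizes = ndimage.sum_labels(data, labels, range(1, n + 1))
        assert out.n_voxels == int(sizes.max())

    def test_empty_stays_empty(self):
        empty = BinaryMask(np.zeros((4, 4, 4), bool), (1, 1, 1))
        assert largest_connected_component(empty).n_voxels == 0

    def test_diagonal_voxels_connect_under_26_connectivity(self):
        data = np.zeros((4, 4, 4), bool)
        data[0, 0, 0] = data[1, 1, 1] = True
        out = largest_connected_component(BinaryMask(data, (1, 1, 1)))
        assert out.n_voxels == 2


class TestResampleMask:
    def test_identity_on_same_grid(self):
        mask = cube_mask(3)
        out = resample_mask(mask, mask.shape, mask.voxel_size_mm)
        assert (out.data == mask.data).all()

    def test_downsample_filled_rectangle(self):
        # 8x8x2 grid at 1 mm -> 4x4x1 at 2 mm: the filled rectangle halves
        data = np.zeros((8, 8, 2), bool)
        data[2:6, 2:6, :] = True
        mask = BinaryMask(data, (1.0, 1.0, 1.0))
        out = resample_mask(mask, (4, 4, 1), (2.0, 2.0, 2.0))
        expected = np.zeros((4, 4, 1), bool)
        expected[1:3, 1:3, 0] = True
        assert (out.data == expected).all()

    def test_empty_mask_stays_empty(self):
        mask = BinaryMask(np.zeros((8, 8, 8), bool), (1, 1, 1))
        assert resample_mask(mask, (4, 4, 4), (2, 2, 2)).n_voxels == 0

    def test_extent_mismatch_rejected(self):
        mask = cube_mask(4)
        with pytest.raises(GeometryError):
            resample_mask(mask, (4, 4, 4), (1.0, 1.0, 1.0))


def _toy_maskset(shape=(20, 20, 20)):
    masks = {}
    for i, lobe in enumerate(LOBE_NAMES):
        data = np.zeros(shape, bool)
        data[2:9, 2 + 2 * i : 9 + 2 * i, 2:9] = True
        masks[lobe] = BinaryMask(data, (1, 1, 1), lobe)
    rv = np.zeros(shape, bool)
    rv[12:17, 12:17, 12:17] = True
    rv[0, 0, 0] = True  # detached speckle
    masks[RV_NAME] = BinaryMask(rv, (1, 1, 1), RV_NAME)
    for name in VESSEL_NAMES:
        masks[name] = BinaryMask(np.zeros(shape, bool), (1, 1, 1), name)
    return masks


class TestBuildVois:
    def test_no_vessels_gives_hollow_shells(self):
        masks = _toy_maskset()
        vois = build_vois(masks, VoiRecipe())
        for lobe in LOBE_NAMES:
            expected = hollow_shell(masks[lobe], 3)
            assert (vois[lobe].data == expected.data).all()

    def test_vessel_tube_removed_with_margin(self):
        masks = _toy_maskset()
        tube = np.zeros((20, 20, 20), bool)
        tube[5, 5, :] = True
        masks[VESSEL_NAMES[0]] = BinaryMask(tube, (1, 1, 1), VESSEL_NAMES[0])
        vois = build_vois(masks, VoiRecipe(vessel_dilation_iters=2))
        expected = subtract(
            hollow_shell(masks["LLL"], 3),
            [dilate(masks[VESSEL_NAMES[0]], 2)],
        )
        expected = largest_connected_component(expected)
        assert (vois["LLL"].data == expected.data).all()

    def test_rv_speckle_removed(self):
        masks = _toy_maskset()
        vois = build_vois(masks, VoiRecipe())
        assert not vois[RV_NAME].data[0, 0, 0]
        assert vois[RV_NAME].n_voxels == 125

    def test_final_vois_subsets_of_inputs(self):
        masks = _toy_maskset()
        vois = build_vois(masks, VoiRecipe())
        for name in LOBE_NAMES + (RV_NAME,):
            assert not (vois[name].data & ~masks[name].data).any()

    def test_missing_mask_rejected(self):
        masks = _toy_maskset()
        del masks["RML"]
        with pytest.raises(KeyError):
            build_vois(masks, VoiRecipe())
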