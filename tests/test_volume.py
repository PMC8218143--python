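"""Volumetric primitives: sagittal flipping, symmetric template, smoothing,
resampling, connected components."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petdti.volume import (BinaryMask, Volume3D, connected_components,
                           default_midline, flip_sagittal, gaussian_smooth,
                           make_symmetric_template, resample, FWHM_TO_SIGMA)

from conftest import centered_affine


class TestFlipSagittal:
    def test_symmetric_volume_is_fixed_point(self, rng):
        shape = (10, 8, 6)
        half = rng.random((5, 8, 6))
        data = np.concatenate([half, half[::-1]], axis=0)
        vol = Volume3D(data, centered_affine(shape))
        out = flip_sagittal(vol, 0.0)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_involution_exact_on_grid_aligned_midline(self, random_volume):
        once = flip_sagittal(random_volume, 0.0)
        twice = flip_sagittal(once, 0.0)
        np.testing.assert_allclose(twice.data, random_volume.data, atol=1e-12)

    def test_single_voxel_reflects_across_midline(self):
        shape = (10, 6, 6)
        aff = centered_affine(shape, spacing=2.0)
        vol = Volume3D(np.zeros(shape), aff)
        # voxel center at world x = midline + 5 mm (voxel centers sit on
        # odd world coordinates for this grid)
        idx = vol.world_to_index([5.0, 1.0, 1.0])[0].round().astype(int)
        vol.data[tuple(idx)] = 7.0
        out = flip_sagittal(vol, 0.0)
        mirror = vol.world_to_index([-5.0, 1.0, 1.0])[0].round().astype(int)
        assert out.data[tuple(mirror)] == pytest.approx(7.0)
        assert out.data[tuple(idx)] == pytest.approx(0.0)

    def test_midline_outside_extent_rejected(self, random_volume):
        with pytest.raises(ValueError, match="midline"):
            flip_sagittal(random_volume, 1e4)

    def test_default_midline_is_central_plane(self, random_volume):
        assert default_midline(random_volume) == pytest.approx(0.0)


class TestSymmetricTemplate:
    def test_symmetric_input_unchanged(self, rng):
        shape = (8, 6, 6)
        half = rng.random((4, 6, 6))
        vol = Volume3D(np.concatenate([half, half[::-1]], axis=0),
                       centered_affine(shape))
        out = make_symmetric_template(vol, 0.0)
        np.testing.assert_allclose(out.data, vol.data, atol=1e-12)

    def test_mirrored_pair_averages(self):
        shape = (8, 6, 6)
        vol = Volume3D(np.zeros(shape), centered_affine(shape))
        vol.data[1, 3, 3] = 10.0
        vol.data[6, 3, 3] = 2.0  # mirror voxel of [1, 3, 3] about x = 0
        out = make_symmetric_template(vol, 0.0)
        assert out.data[1, 3, 3] == pytest.approx(6.0)
        assert out.data[6, 3, 3] == pytest.approx(6.0)

    def test_output_is_flip_invariant(self, random_volume):
        tmpl = make_symmetric_template(random_volume, 0.0)
        flipped = flip_sagittal(tmpl, 0.0)
        np.testing.assert_allclose(flipped.data, tmpl.data, atol=1e-12)


class TestGaussianSmooth:
    def test_fwhm_sigma_identity(self):
        assert 2.0 * FWHM_TO_SIGMA == pytest.approx(0.8493, abs=5e-5)

    def test_constant_volume_unchanged(self):
        vol = Volume3D(np.full((8, 8, 8), 3.5), centered_affine((8, 8, 8)))
        out = gaussian_smooth(vol, 4.0)
        np.testing.assert_allclose(out.data, 3.5, rtol=1e-12)

    def test_zero_fwhm_is_identity(self, random_volume):
        out = gaussian_smooth(random_volume, 0.0)
        np.testing.assert_array_equal(out.data, random_volume.data)

    def test_sum_preserved_for_interior_signal(self, rng):
        shape = (24, 24, 24)
        data = np.zeros(shape)
        data[8:16, 8:16, 8:16] = rng.random((8, 8, 8))
        vol = Volume3D(data, centered_affine(shape))
        out = gaussian_smooth(vol, 4.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-3)

    def test_anisotropic_spacing_sigma(self, rng):
        # a volume with 1x2x4 mm voxels: smoothing must be isotropic in
        # world space, so a world-symmetric blob stays world-symmetric
        aff = np.diag([1.0, 2.0, 4.0, 1.0])
        data = np.zeros((32, 16, 8))
        data[16, 8, 4] = 1.0
        out = gaussian_smooth(Volume3D(data, aff), 8.0)
        # world-space profile at +-4 mm along each axis must match
        assert out.data[20, 8, 4] == pytest.approx(out.data[16, 10, 4], rel=1e-6)
        assert out.data[20, 8, 4] == pytest.approx(out.data[16, 8, 5], rel=1e-6)

    def test_negative_fwhm_rejected(self, random_volume):
        with pytest.raises(ValueError):
            gaussian_smooth(random_volume, -1.0)


def _bfs_components(mask, connectivity):
    """Brute-force BFS labeling oracle."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    seen = np.zeros(mask.shape, dtype=bool)
    sizes = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for off in offsets:
                n = tuple(np.add(v, off))
                if (all(0 <= n[i] < mask.shape[i] for i in range(3))
                        and mask[n] and not seen[n]):
                    seen[n] = True
                    stack.append(n)
        sizes.append(size)
    return sorted(sizes, reverse=True)


class TestConnectedComponents:
    def test_two_disjoint_blobs(self):
        data = np.zeros((8, 8, 8), dtype=bool)
        data[1, 1, 1:3] = True
        data[5, 5, 5:7] = True
        comps = connected_components(BinaryMask(data, np.eye(4)))
        assert [c.size for c in comps] == [2, 2]
        # tie broken by smallest linear index
        assert comps[0].min_linear_index < comps[1].min_linear_index

    def test_single_voxel(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[2, 2, 2] = True
        comps = connected_components(BinaryMask(data, np.eye(4)))
        assert len(comps) == 1 and comps[0].size == 1

    def test_diagonal_touching_depends_on_connectivity(self):
        data = np.zeros((4, 4, 4), dtype=bool)
        data[1, 1, 1] = data[2, 2, 2] = True
        n26 = len(connected_components(BinaryMask(data, np.eye(4), 26)))
        n6 = len(connected_components(BinaryMask(data, np.eye(4), 6)))
        assert (n26, n6) == (1, 2)

    def test_empty_mask(self):
        comps = connected_components(
            BinaryMask(np.zeros((3, 3, 3), dtype=bool), np.eye(4)))
        assert comps == []

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_bfs_oracle_on_random_masks(self, connectivity, rng):
        for _ in range(4):
            mask = rng.random((12, 12, 12)) < 0.25
            comps = connected_components(BinaryMask(mask, np.eye(4), connectivity))
            assert [c.size for c in comps] == _bfs_components(mask, connectivity)


class TestResample:
    def test_identity_at_same_spacing(self, random_volume):
        out = resample(random_volume, random_volume.spacing)
        assert out.shape == random_volume.shape
        np.testing.assert_allclose(out.data, random_volume.data, atol=1e-10)

    def test_constant_volume_any_spacing(self):
        vol = Volume3D(np.full((8, 8, 8), 2.0), centered_affine((8, 8, 8)))
        out = resample(vol, 0.7)
        np.testing.assert_allclose(out.data, 2.0, rtol=1e-10)

    def test_upsampling_doubles_dimensions(self):
        vol = Volume3D(np.zeros((10, 12, 14)), centered_affine((10, 12, 14), 2.0))
        out = resample(vol, 1.0)
        assert all(abs(n - 2 * o) <= 1 for n, o in zip(out.shape, vol.shape))
        np.testing.assert_allclose(out.spacing, 1.0)

    def test_world_position_of_content_preserved(self):
        vol = Volume3D(np.zeros((16, 16, 16)), centered_affine((16, 16, 16), 2.0))
        # voxel centers sit on odd world coordinates for this grid
        idx = vol.world_to_index([5.0, -7.0, 3.0])[0].round().astype(int)
        vol.data[tuple(idx)] = 1.0
        out = resample(vol, 1.0)
        peak = np.unravel_index(np.argmax(out.data), out.shape)
        peak_world = out.index_to_world(np.asarray(peak, dtype=float))[0]
        np.testing.assert_allclose(peak_world, [5.0, -7.0, 3.0], atol=1.0)

    def test_nonpositive_spacing_rejected(self, random_volume):
        with pytest.raises(ValueError):
            resample(random_volume, 0.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_flip_involution_property(seed):
    """flip . flip == identity for arbitrary volumes on grid-aligned midlines."""
    r = np.random.default_rng(seed)
    shape = (2 * int(r.integers(2, 7)), int(r.integers(2, 8)), int(r.integers(2, 8)))
    vol = Volume3D(r.normal(size=shape), centered_affine(shape, 2.0))
    out = flip_sagittal(flip_sagittal(vol, 0.0), 0.0)
    np.testing.assert_allclose(out.data, vol.data, atol=1e-12)
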