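"""Fit layer, unit selection, substitution, averaging, and iteration."""

import numpy as np
import pytest

from edgeup.enhance import (
    VolumeGrid,
    average_resample,
    best_fit,
    detect_edges,
    enhance,
    fit_unit,
    replicate_upsample,
    _select_units,
)
from edgeup.phantom import ground_truth_mask_on, segment_halfmax
from edgeup.units import block_mean


def _ssr_direct(I, e, K, B):
    return float(((I.reshape(-1) - K * e.reshape(-1) - B) ** 2).sum())


class TestFitUnit:
    def test_exact_identity(self, small_library):
        _, lo = small_library[5]
        K, B, ssr = fit_unit(lo.values, lo)
        assert (K, B) == pytest.approx((1.0, 0.0), abs=1e-12)
        assert ssr == pytest.approx(0.0, abs=1e-12)

    def test_affine_exact(self, small_library):
        _, lo = small_library[5]
        K, B, ssr = fit_unit(2.0 * lo.values + 3.0, lo)
        assert (K, B) == pytest.approx((2.0, 3.0), abs=1e-12)
        assert ssr == pytest.approx(0.0, abs=1e-10)

    def test_constant_neighborhood(self, small_library):
        _, lo = small_library[0]
        K, B, ssr = fit_unit(np.full((3, 3, 3), 5.0), lo)
        assert (K, B, ssr) == (0.0, 5.0, 0.0)

    def test_matches_grid_search_oracle(self, small_library, rng):
        """Closed form agrees with a dense brute-force minimizer of the SSR."""
        for _ in range(5):
            I = rng.normal(0, 1, (3, 3, 3))
            idx = int(rng.integers(len(small_library)))
            _, lo = small_library[idx]
            K, B, ssr = fit_unit(I, lo)
            assert ssr == pytest.approx(_ssr_direct(I, lo.values, K, B), abs=1e-10)
            ks = K + np.linspace(-0.5, 0.5, 41)
            bs = B + np.linspace(-0.5, 0.5, 41)
            grid = np.array([[_ssr_direct(I, lo.values, k, b) for b in bs] for k in ks])
            assert grid.min() >= ssr - 1e-9

    def test_perturbation_never_improves(self, small_library, rng):
        """(K, B) is a true minimum: +-eps perturbations only increase SSR."""
        I = rng.normal(0, 1, (3, 3, 3))
        _, lo = small_library[17]
        K, B, ssr = fit_unit(I, lo)
        for dk in (-1e-3, 0, 1e-3):
            for db in (-1e-3, 0, 1e-3):
                assert _ssr_direct(I, lo.values, K + dk, B + db) >= ssr - 1e-12

    def test_degenerate_unit_falls_back(self):
        K, B, ssr = fit_unit(np.arange(27.0).reshape(3, 3, 3), np.ones((3, 3, 3)))
        assert K == 0.0
        assert B == pytest.approx(13.0)

    def test_rejects_bad_neighborhood(self, small_library):
        with pytest.raises(ValueError):
            fit_unit(np.full((3, 3, 3), np.nan), small_library[0][1])


class TestBestFit:
    def test_library_unit_recovered(self, small_library):
        _, lo = small_library[40]
        res = best_fit(lo.values, small_library)
        assert res.SSR == pytest.approx(0.0, abs=1e-12)
        # any SSR-0 tie resolves to the lowest index; check reconstruction
        K, B, _ = fit_unit(lo.values, small_library[res.unit_index][1])
        rec = K * small_library.low[res.unit_index] + B
        assert np.allclose(rec, lo.values.reshape(-1), atol=1e-9)

    def test_constant_neighborhood_lowest_index(self, small_library):
        res = best_fit(np.full((3, 3, 3), 7.0), small_library)
        assert res.unit_index == 0
        assert res.K == pytest.approx(0.0, abs=1e-12)
        assert res.B == pytest.approx(7.0)

    def test_fast_path_matches_exhaustive(self, small_library, rng):
        """Vectorized selection equals the per-unit reference on random data."""
        neigh = rng.normal(0, 1, (400, 27))
        centered = neigh - neigh.mean(axis=1, keepdims=True)
        fast = _select_units(centered, small_library, tie_rel=1e-2)
        for i in range(len(neigh)):
            ref = best_fit(neigh[i].reshape(3, 3, 3), small_library)
            assert ref.unit_index == fast[i]


def _grid(data, voxel=0.8):
    return VolumeGrid(data=np.asarray(data, dtype=float), voxel_size_mm=voxel)


class TestDetectEdges:
    def test_constant_volume(self, small_library):
        out = detect_edges(_grid(np.full((4, 4, 4), 2.5)), small_library)
        assert out.shape == (8, 8, 8)
        assert np.allclose(out.data, 2.5)
        assert out.voxel_size_mm == pytest.approx(0.4)
        assert out.resolution_level == "high"

    def test_small_volume_rejected(self, small_library):
        with pytest.raises(ValueError):
            detect_edges(_grid(np.zeros((2, 5, 5))), small_library)

    def test_unit_tile_reproduced(self, small_library):
        """A volume equal to a unit's downsample yields that unit's center."""
        hi, lo = small_library[40]
        out = detect_edges(_grid(lo.values), small_library)
        c = hi.pattern[2:4, 2:4, 2:4]
        assert np.allclose(out.data[2:4, 2:4, 2:4], c, atol=1e-9)

    def test_noiseless_phantom_snaps_to_truth(
        self, axis_library, phantom_volume, phantom_spec
    ):
        """The sigma->0 limit: thresholded output equals the exact cube mask."""
        out = detect_edges(phantom_volume, axis_library)
        seg = segment_halfmax(out)
        truth = ground_truth_mask_on(out, phantom_spec)
        assert np.array_equal(seg.mask, truth.mask)

    def test_world_coordinates_preserved(self, small_library):
        vol = _grid(np.random.default_rng(0).normal(size=(6, 6, 6)))
        out = detect_edges(vol, small_library)
        assert np.allclose(vol.center_world(), out.center_world(), atol=1e-9)


class TestAverageResample:
    def test_constant_preserved(self):
        vol = VolumeGrid(np.full((8, 8, 8), 1.5), voxel_size_mm=0.4,
                         resolution_level="high")
        for off in [(0, 0, 0), (1, 1, 1), (-1, 0, 1)]:
            out = average_resample(vol, off)
            assert out.shape == (4, 4, 4)
            assert np.allclose(out.data, 1.5)

    def test_zero_offset_is_block_mean(self, small_library, rng):
        hi = detect_edges(_grid(rng.normal(size=(5, 5, 5))), small_library)
        out = average_resample(hi, (0, 0, 0))
        assert np.allclose(out.data, block_mean(hi.data), atol=1e-15)

    def test_interior_mean_preserved(self, rng):
        """Cell means conserve the global mean away from padded borders."""
        data = rng.normal(size=(12, 12, 12))
        vol = VolumeGrid(data, voxel_size_mm=0.4, resolution_level="high")
        out = average_resample(vol, (1, 1, 1))
        # cells [0..4] per axis average high-res voxels [1..10]: no padding
        inner_out = out.data[:5, :5, :5]
        inner_in = data[1:11, 1:11, 1:11]
        assert inner_out.mean() == pytest.approx(inner_in.mean(), abs=1e-12)

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError):
            average_resample(
                VolumeGrid(np.zeros((7, 8, 8)), voxel_size_mm=0.4), (0, 0, 0)
            )

    def test_offset_range_enforced(self):
        vol = VolumeGrid(np.zeros((8, 8, 8)), voxel_size_mm=0.4)
        with pytest.raises(ValueError):
            average_resample(vol, (2, 0, 0))

    def test_world_shift_recorded(self):
        vol = VolumeGrid(np.zeros((8, 8, 8)), voxel_size_mm=0.4,
                         resolution_level="high")
        out = average_resample(vol, (1, 1, 1))
        # cell 0 center sits at high-res index 1.5 -> 0.4 * 1.5 mm
        assert np.allclose(out.voxel_to_world((0, 0, 0)), 0.4 * 1.5)


class TestEnhance:
    def test_single_iteration_is_detection(self, small_library, phantom_volume):
        a = enhance(phantom_volume, small_library, n_iterations=1)
        b = detect_edges(phantom_volume, small_library)
        assert np.array_equal(a.data, b.data)
        assert np.allclose(a.affine, b.affine)

    def test_bad_iteration_count(self, small_library, phantom_volume):
        with pytest.raises(ValueError):
            enhance(phantom_volume, small_library, n_iterations=0)

    def test_noiseless_fixed_point(self, axis_library, phantom_volume, phantom_spec):
        """Iterations 1 and 3 give identical thresholded masks (no drift)."""
        outs = enhance(phantom_volume, axis_library, n_iterations=3,
                       snapshots=(1, 3))
        masks = {}
        for k, out in outs.items():
            seg = segment_halfmax(out)
            truth = ground_truth_mask_on(out, phantom_spec)
            assert np.array_equal(seg.mask, truth.mask)
            masks[k] = seg.mask
        assert np.array_equal(masks[1], masks[3])

    def test_polarity_antisymmetry(self, small_library, rng):
        """Negating the input exactly negates the output (sign-free K)."""
        data = rng.normal(0, 1, (6, 6, 6))
        pos = enhance(_grid(data), small_library, n_iterations=2)
        neg = enhance(_grid(-data), small_library, n_iterations=2)
        assert np.array_equal(neg.data, -pos.data)

    def test_resolution_contract(self, small_library, phantom_volume):
        out = enhance(phantom_volume, small_library, n_iterations=2)
        assert out.shape == tuple(2 * n for n in phantom_volume.shape)
        assert out.voxel_size_mm == pytest.approx(phantom_volume.voxel_size_mm / 2)
        # world position of the ROI center preserved to < 1 high-res voxel
        drift = np.abs(out.center_world() - phantom_volume.center_world())
        assert (drift < out.voxel_size_mm).all()

    def test_snapshots_match_standalone_runs(self, small_library, phantom_volume,
                                             rng):
        noisy = VolumeGrid(
            phantom_volume.data + rng.normal(0, 0.25, phantom_volume.shape),
            voxel_size_mm=phantom_volume.voxel_size_mm,
        )
        snaps = enhance(noisy, small_library, n_iterations=4, snapshots=(2, 4))
        solo = enhance(noisy, small_library, n_iterations=2)
        assert np.array_equal(snaps[2].data, solo.data)


class TestReplicateUpsample:
    def test_blocks_copy_values(self, phantom_volume):
        up = replicate_upsample(phantom_volume)
        assert up.shape == tuple(2 * n for n in phantom_volume.shape)
        assert np.array_equal(up.data[::2, ::2, ::2], phantom_volume.data)
        assert np.array_equal(up.data[1::2, 1::2, 1::2], phantom_volume.data)
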