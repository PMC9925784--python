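import numpy as np
import pytest
from scipy import ndimage

from lsmosaic.acquisition import RawStrip, acquire_strip
from lsmosaic.errors import ConfigError, DataError
from lsmosaic.geometry import MOSAIC0_5, MOSAIC4, MOSAIC16
from lsmosaic.reconstruction import (
    ShiftEstimate,
    _phase_correlation,
    deskew,
    fuse,
    globalize_shifts,
    mip_slabs,
    phase_correlate,
    reslice,
)
from lsmosaic.volumes import DeskewedVolume, IntensityVolume


def smooth_tile(rng, shape=(64, 64, 48), origin=(0.0, 0.0, 0.0)):
    vals = ndimage.gaussian_filter(rng.random(shape).astype(np.float32), 1.5)
    return DeskewedVolume(vals, (1.0, 1.0, 1.0), origin=np.asarray(origin, float))


class TestDeskew:
    @pytest.mark.parametrize(
        "preset,expected",
        [
            (MOSAIC16, (16.4049, 16.4049, 16.4049)),
            (MOSAIC4, (4.1012, 4.1012, 4.1012)),
            (MOSAIC0_5, (0.5127, 0.725, 0.5127)),
        ],
    )
    def test_output_spacing_per_preset(self, preset, expected):
        geom = preset.binned_geometry(frame_shape=(128, 128))
        strip = RawStrip(np.zeros((8, *geom.frame_shape), np.float32), geom)
        vol = deskew(strip)
        assert vol.spacing == pytest.approx(expected, abs=5e-4)
        if preset is not MOSAIC0_5:
            assert np.ptp(vol.spacing) / vol.spacing[0] < 1e-6

    def test_zero_strip_gives_background_volume(self):
        geom = MOSAIC16.binned_geometry(frame_shape=(128, 128))
        strip = RawStrip(np.zeros((10, 2, 2), np.float32), geom)
        vol = deskew(strip)
        assert np.all(vol.values == 0.0)

    def test_point_source_round_trips_within_one_voxel(self):
        pitch = 1.5
        vals = np.zeros((160, 60, 60), dtype=np.float32)
        vals[80, 30, 30] = 1000.0
        volume = IntensityVolume(vals, pitch, origin=np.full(3, 0.5 * pitch))
        w_true = np.array([80.5, 30.5, 30.5]) * pitch
        # raw sensor sized so the binned frames are 44 × 44
        geom = MOSAIC4.binned_geometry(frame_shape=(44 * 11, 44 * 16))
        shear = geom.pitch_depth * geom.frame_shape[1] * geom.cos_tilt
        strip = acquire_strip(volume, geom, (-shear, 0.0, 0.0), 240.0 + shear)
        dsk = deskew(strip)
        idx = np.unravel_index(int(np.argmax(dsk.values)), dsk.shape)
        w_found = dsk.index_to_world(np.asarray(idx))
        assert np.all(np.abs(w_found - w_true) <= np.asarray(dsk.spacing))


class TestPhaseCorrelation:
    def test_tile_against_itself(self, rng):
        tile = smooth_tile(rng)
        est = phase_correlate(tile, tile, (0, 1))
        assert est.shift_um == pytest.approx((0.0, 0.0, 0.0), abs=1e-6)
        assert est.score == pytest.approx(1.0, abs=1e-6)

    def test_known_integer_shift_recovered_exactly(self, rng):
        big = ndimage.gaussian_filter(rng.random((96, 96, 64)).astype(np.float32), 1.5)
        a = big[8:72, 8:72, 8:56]
        b = big[8 + 5 : 72 + 5, 8 - 3 : 72 - 3, 8 + 2 : 56 + 2]
        d, score = _phase_correlation(a, b, (16, 16, 12))
        assert tuple(d) == (-5.0, 3.0, -2.0)  # returns -displacement
        assert score > 0.2

    def test_noisy_shift_recovered_within_one_voxel(self):
        failures = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            big = ndimage.gaussian_filter(
                rng.random((80, 80, 48)).astype(np.float32), 1.5
            )
            a = big[8:56, 8:56, 4:44].copy()
            b = big[8 + 4 : 56 + 4, 8 - 2 : 56 - 2, 4 + 1 : 44 + 1].copy()
            snr = 10.0
            a += rng.normal(0, a.std() / snr, a.shape).astype(np.float32)
            b += rng.normal(0, b.std() / snr, b.shape).astype(np.float32)
            d, _ = _phase_correlation(a, b, (12, 12, 10))
            failures += not np.all(np.abs(d - (-4.0, 2.0, -1.0)) <= 1.0)
        assert failures == 0

    def test_agrees_with_skimage_reference(self, rng):
        # independent oracle: scikit-image's phase correlation on the same
        # noise-free shifted crops
        from skimage.registration import phase_cross_correlation

        a = ndimage.gaussian_filter(rng.random((64, 64, 48)).astype(np.float32), 1.5)
        b = np.roll(a, (4, 6, -3), axis=(0, 1, 2))  # periodic shift
        ours, _ = _phase_correlation(a, b, (16, 16, 12))
        ref, _, _ = phase_cross_correlation(a, b, normalization="phase")
        # conventions differ in sign: ref reports the shift moving b onto a
        assert np.allclose(ours, -ref)

    def test_degenerate_overlap_flagged(self):
        flat = DeskewedVolume(np.zeros((48, 48, 48), np.float32), (1, 1, 1))
        est = phase_correlate(flat, flat, (0, 1))
        assert est.degenerate and est.score == 0.0

    def test_insufficient_overlap_rejected(self, rng):
        a = smooth_tile(rng, origin=(0, 0, 0))
        b = smooth_tile(rng, origin=(60.0, 0, 0))  # only 4 voxels overlap
        with pytest.raises(DataError):
            phase_correlate(a, b, (0, 1))


class TestGlobalize:
    def test_single_tile_nominal(self):
        layout = globalize_shifts([], 1, np.zeros((1, 3)))
        assert np.array_equal(layout.offsets_um, np.zeros((1, 3)))

    def test_chain_cumulative_sums(self):
        nominal = np.zeros((3, 3))
        ests = [
            ShiftEstimate((0, 1), (10.0, 0.0, 1.0), 1.0),
            ShiftEstimate((1, 2), (-4.0, 2.0, 0.5), 1.0),
        ]
        layout = globalize_shifts(ests, 3, nominal)
        assert layout.offsets_um[1] == pytest.approx((10.0, 0.0, 1.0))
        assert layout.offsets_um[2] == pytest.approx((6.0, 2.0, 1.5))
        assert layout.residual_norm == pytest.approx(0.0, abs=1e-9)

    def test_inconsistent_triangle_matches_dense_solver(self):
        eps = 0.9
        ests = [
            ShiftEstimate((0, 1), (1.0, 0.0, 0.0), 1.0),
            ShiftEstimate((1, 2), (1.0, 0.0, 0.0), 1.0),
            ShiftEstimate((0, 2), (2.0 + eps, 0.0, 0.0), 1.0),
        ]
        layout = globalize_shifts(ests, 3, np.zeros((3, 3)))
        # oracle: unweighted least squares with t0 = 0 solved densely
        a = np.array([[-1, 1, 0], [0, -1, 1], [-1, 0, 1]], float)[:, 1:]
        b = np.array([1.0, 1.0, 2.0 + eps])
        sol, *_ = np.linalg.lstsq(a, b, rcond=None)
        assert layout.offsets_um[1:, 0] == pytest.approx(sol, abs=1e-6)
        resid = np.abs(layout.residuals_um[:, 0])
        assert resid.sum() == pytest.approx(abs(eps), rel=1e-6)

    def test_disconnected_graph_reported(self):
        ests = [ShiftEstimate((0, 1), (1.0, 0, 0), 1.0)]
        with pytest.raises(DataError, match="components"):
            globalize_shifts(ests, 4, np.zeros((4, 3)))


class TestFuse:
    def test_single_tile_identity(self, rng):
        tile = smooth_tile(rng)
        fused = fuse([tile])
        assert np.allclose(fused.values, tile.values, atol=1e-6)

    def test_two_constant_tiles_fuse_to_constant(self):
        a = DeskewedVolume(np.full((40, 40, 20), 5.0, np.float32), (1, 1, 1),
                           origin=np.zeros(3))
        b = DeskewedVolume(np.full((40, 40, 20), 5.0, np.float32), (1, 1, 1),
                           origin=np.array([20.0, 0.0, 0.0]))
        fused = fuse([a, b])
        assert np.allclose(fused.values[fused.valid], 5.0, atol=1e-6)

    def test_fused_voxels_are_convex_combinations(self):
        a = DeskewedVolume(np.full((40, 40, 20), 2.0, np.float32), (1, 1, 1),
                           origin=np.zeros(3))
        b = DeskewedVolume(np.full((40, 40, 20), 8.0, np.float32), (1, 1, 1),
                           origin=np.array([20.0, 0.0, 0.0]))
        fused = fuse([a, b])
        vals = fused.values[fused.valid]
        assert vals.min() >= 2.0 - 1e-6 and vals.max() <= 8.0 + 1e-6

    def test_idempotent_on_identical_overlapping_data(self, rng):
        base = smooth_tile(rng, shape=(60, 40, 20))
        a = DeskewedVolume(base.values[:40].copy(), (1, 1, 1), origin=np.zeros(3))
        b = DeskewedVolume(base.values[20:].copy(), (1, 1, 1),
                           origin=np.array([20.0, 0.0, 0.0]))
        fused = fuse([a, b])
        assert np.allclose(fused.values, base.values, atol=1e-5)

    def test_spacing_mismatch_rejected(self, rng):
        a = smooth_tile(rng)
        b = DeskewedVolume(a.values.copy(), (2.0, 1.0, 1.0))
        with pytest.raises(DataError):
            fuse([a, b])


class TestProjections:
    def test_constant_volume_constant_mip(self):
        vol = DeskewedVolume(np.full((30, 20, 10), 3.0, np.float32), (1, 1, 1))
        mips = mip_slabs(vol, axis=2, slab_um=5.0)
        assert np.all(mips == 3.0) and mips.shape == (2, 30, 20)

    def test_single_bright_voxel_in_exactly_one_slab(self):
        vals = np.zeros((30, 20, 12), np.float32)
        vals[4, 5, 7] = 9.0
        vol = DeskewedVolume(vals, (1, 1, 1))
        mips = mip_slabs(vol, axis=2, slab_um=4.0)
        assert (mips.max(axis=(1, 2)) == 9.0).sum() == 1

    def test_50um_slab_at_mosaic16_spacing_is_3_slices(self):
        g = MOSAIC16.iso_spacing
        vol = DeskewedVolume(np.zeros((10, 10, 10), np.float32), (g, g, g))
        assert int(50.0 // g) == 3
        mips = mip_slabs(vol, axis=0, slab_um=50.0)
        assert mips.shape[0] == int(np.ceil(10 / 3))

    def test_reslice_permutes_without_interpolation(self, rng):
        tile = smooth_tile(rng, shape=(12, 10, 8))
        yz = reslice(tile, (2, 1, 0))
        assert yz.shape == (8, 10, 12)
        assert np.array_equal(yz.values, np.transpose(tile.values, (2, 1, 0)))
        with pytest.raises(ConfigError):
            reslice(tile, (0, 0, 1))
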