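import numpy as np
import pandas as pd
import pytest

from lsmosaic.errors import ConfigError, DataError
from lsmosaic.phantom import Appearance, render_phantom
from lsmosaic.quantification import (
    EXCLUDED,
    UNASSIGNED,
    SegmentationResult,
    assign_layers,
    compute_densities,
    correct_density,
    filter_morphology,
    filter_segments,
    measure_shrinkage,
    segment_blobs,
    summarize_shrinkage,
)
from tests.conftest import make_cells


class TestMorphologyFilter:
    def test_constant_volume_maps_to_zero(self):
        vol = np.full((40, 40, 40), 17.0, dtype=np.float32)
        out = filter_morphology(vol, 5.0, 1.0)
        assert np.allclose(out, 0.0)
        assert out.min() >= 0

    def test_soma_preserved_background_removed(self, single_sphere_volume):
        vol = single_sphere_volume
        out = filter_morphology(vol.values, 6.0, 1.0)
        peak_in = float(vol.values.max() - vol.background)
        assert out.max() == pytest.approx(peak_in, rel=0.1)
        assert abs(float(out[0, 0, 0])) < 1e-6

    def test_translation_equivariance(self, rng):
        vol = rng.random((40, 40, 40)).astype(np.float32)
        out = filter_morphology(vol, 3.0, 1.0)
        shifted = filter_morphology(np.roll(vol, 5, axis=0), 3.0, 1.0)
        # compare away from the wrap-around border (roll + footprint reach)
        assert np.allclose(np.roll(out, 5, axis=0)[12:-12], shifted[12:-12], atol=1e-5)


class TestSegmentBlobs:
    def test_empty_volume_yields_empty_table(self):
        res = segment_blobs(np.zeros((30, 30, 30), np.float32), 1.0)
        assert res.table.empty

    def test_single_sphere_volume_within_15_percent(self, single_sphere_volume):
        res = segment_blobs(single_sphere_volume.values - 10.0, 1.0)
        assert len(res.table) == 1
        analytic = 4.0 / 3.0 * np.pi * 4.0**3
        assert res.table.volume_um3.iloc[0] == pytest.approx(analytic, rel=0.15)

    @pytest.mark.parametrize("separation,expected", [(20.0, 2), (6.0, 2)])
    def test_sphere_pairs_resolved(self, separation, expected):
        x0 = 25.0 - separation / 2
        cells = make_cells([(x0, 25.0, 25.0, 3.0), (x0 + separation, 25.0, 25.0, 3.0)])
        vol = render_phantom(cells, np.array([[0.0, 50.0]] * 3), 1.0, Appearance())
        res = segment_blobs(vol.values - 10.0, 1.0)
        assert len(res.table) == expected

    def test_centroid_in_world_coordinates(self, single_sphere_volume):
        res = segment_blobs(
            single_sphere_volume.values - 10.0, 1.0, origin=(100.0, 0.0, 0.0)
        )
        assert res.table.x_um.iloc[0] == pytest.approx(125.0, abs=0.5)
        assert res.table.y_um.iloc[0] == pytest.approx(25.0, abs=0.5)


class TestSizeFilter:
    def test_strictly_greater_than_boundary(self):
        table = pd.DataFrame({
            "segment_id": [1, 2, 3],
            "volume_um3": [124.9, 125.0, 125.1],
        })
        kept = filter_segments(table)
        assert kept.volume_um3.tolist() == [125.1]

    def test_empty_table_passthrough(self):
        table = pd.DataFrame(columns=["segment_id", "volume_um3"])
        assert filter_segments(table).empty

    def test_matches_brute_force_on_random_volumes(self, rng):
        vols = rng.uniform(50.0, 200.0, size=1000)
        table = pd.DataFrame({"segment_id": np.arange(1000), "volume_um3": vols})
        kept = filter_segments(table)
        assert len(kept) == sum(1 for v in vols if v > 125.0)


def two_layer_segmentation():
    """Two somata: one inside layer 1, one straddling the layer boundary."""
    labels_img = np.zeros((40, 20, 40), dtype=np.int32)
    labels_img[10:14, 8:12, 8:12] = 1   # wholly inside layer A (z < 20)
    labels_img[20:24, 8:12, 18:22] = 2  # straddles the z=20 boundary
    layer_labels = np.ones((40, 20, 40), dtype=np.uint8)
    layer_labels[:, :, 20:] = 2
    table = pd.DataFrame({
        "segment_id": [1, 2],
        "x_um": [12.0, 22.0], "y_um": [10.0, 10.0], "z_um": [10.0, 20.0],
        "volume_um3": [64.0, 64.0], "voxels": [64, 64],
        "layer": [UNASSIGNED, UNASSIGNED],
    })
    return SegmentationResult(table=table, label_image=labels_img,
                              spacing=(1.0, 1.0, 1.0)), layer_labels


class TestAssignLayers:
    def test_full_containment_and_straddle(self):
        seg, layer_labels = two_layer_segmentation()
        out = assign_layers(seg, layer_labels, ["A", "B"])
        assert out.set_index("segment_id").layer.to_dict() == {1: "A", 2: UNASSIGNED}

    def test_excluded_region(self):
        seg, layer_labels = two_layer_segmentation()
        excluded = np.zeros_like(layer_labels, dtype=bool)
        excluded[10:14, 8:12, 8:12] = True
        out = assign_layers(seg, layer_labels, ["A", "B"], excluded_mask=excluded)
        assert out.set_index("segment_id").layer[1] == EXCLUDED

    def test_border_touching_excluded(self):
        labels_img = np.zeros((20, 20, 20), dtype=np.int32)
        labels_img[0:3, 5:8, 5:8] = 1  # touches the x=0 face
        table = pd.DataFrame({
            "segment_id": [1], "x_um": [1.0], "y_um": [6.0], "z_um": [6.0],
            "volume_um3": [27.0], "voxels": [27], "layer": [UNASSIGNED],
        })
        seg = SegmentationResult(table=table, label_image=labels_img,
                                 spacing=(1.0, 1.0, 1.0))
        out = assign_layers(seg, np.ones_like(labels_img, np.uint8), ["A"])
        assert out.layer.iloc[0] == EXCLUDED

    def test_shape_mismatch_rejected(self):
        seg, _ = two_layer_segmentation()
        with pytest.raises(DataError):
            assign_layers(seg, np.ones((5, 5, 5), np.uint8), ["A"])


class TestDensities:
    def make_table(self, counts):
        rows = []
        for layer, n in counts.items():
            for i in range(n):
                rows.append((f"{layer}{i}", layer))
        return pd.DataFrame(rows, columns=["segment_id", "layer"])

    def test_simple_density(self):
        # 500 cells in 0.005 mm³ -> 100,000 cells/mm³
        layer_labels = np.ones((100, 100, 500), dtype=np.uint8)  # 5e6 µm³ at 1 µm
        table = self.make_table({"IV": 500})
        rep = compute_densities(table, layer_labels, ["IV"], 1.0)
        assert rep.table.density_per_mm3.iloc[0] == pytest.approx(100000.0)

    def test_pooling_over_disconnected_patches(self):
        # two patches of layer V: 30 cells in 3e5 µm³ + 20 in 2e5 µm³
        layer_labels = np.zeros((100, 100, 100), dtype=np.uint8)
        layer_labels[:, :, :30] = 1
        layer_labels[:, :, 80:] = 1
        table = self.make_table({"V": 50})
        rep = compute_densities(table, layer_labels, ["V"], 1.0)
        assert rep.table.density_per_mm3.iloc[0] == pytest.approx(100000.0)

    def test_pooled_density_is_volume_weighted_mean(self, rng):
        # pooling identity: density of the union equals the volume-weighted
        # mean of patch densities
        v1, v2 = 3e5, 2e5
        n1, n2 = 37, 12
        d1, d2 = n1 / (v1 * 1e-9), n2 / (v2 * 1e-9)
        pooled = (n1 + n2) / ((v1 + v2) * 1e-9)
        weighted = (d1 * v1 + d2 * v2) / (v1 + v2)
        assert pooled == pytest.approx(weighted)

    def test_zero_volume_with_count_is_error(self):
        table = self.make_table({"IV": 3})
        with pytest.raises(DataError):
            compute_densities(table, np.zeros((5, 5, 5), np.uint8), ["IV"], 1.0)


class TestOvercountCorrection:
    @pytest.mark.parametrize(
        "density,corrected",
        [(81903, 67980), (77807, 64580), (86579, 71861)],
    )
    def test_published_corrections(self, density, corrected):
        assert correct_density(density, 0.17) == corrected

    def test_zero_rate_identity(self):
        assert correct_density(81903, 0.0) == 81903

    def test_monotone_decreasing_in_rate(self):
        rates = np.linspace(0.0, 0.9, 10)
        vals = [correct_density(81903.0, r) for r in rates]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_invalid_rate_rejected(self):
        with pytest.raises(ConfigError):
            correct_density(1000.0, 1.0)
        with pytest.raises(ConfigError):
            correct_density(1000.0, -0.1)


class TestShrinkage:
    unit_square = [(0, 0), (1, 0), (1, 1), (0, 1)]

    def test_identical_polygons_zero(self):
        rec = measure_shrinkage(self.unit_square, self.unit_square)
        assert rec.reduction_percent == pytest.approx(0.0)

    def test_12_percent_area_reduction(self):
        s = np.sqrt(0.88)
        shrunk = [(x * s, y * s) for x, y in self.unit_square]
        rec = measure_shrinkage(self.unit_square, shrunk)
        assert rec.reduction_percent == pytest.approx(12.0)
        assert summarize_shrinkage([rec, rec]) == pytest.approx(12.0)

    def test_expansion_reported_negative(self):
        grown = [(x * 1.1, y * 1.1) for x, y in self.unit_square]
        rec = measure_shrinkage(self.unit_square, grown)
        assert rec.reduction_percent < 0

    def test_self_intersecting_polygon_rejected(self):
        bowtie = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(DataError):
            measure_shrinkage(bowtie, self.unit_square)
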