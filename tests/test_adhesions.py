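import numpy as np
import pytest

from faquant import (FAObject, MicroImage, MorphologyConfig, SceneParams,
                     UnassignedRegionError, ValidationError, bin_random,
                     classify_region, generate_fa_scene, partition_regions,
                     pearson_per_object, segment_fas)
from faquant.imageops import LabelMask


def _match_truth(scene, labels):
    """IoU of each truth object with its best-overlapping detection."""
    tl, dl = scene.truth_labels.labels, labels.labels
    out = {}
    for k in scene.truth_areas:
        sel = tl == k
        counts = np.bincount(dl[sel].ravel())
        counts[0] = 0
        j = counts.argmax() if counts.size > 1 else 0
        if j == 0:
            out[k] = (0.0, np.nan)
            continue
        det = dl == j
        iou = (sel & det).sum() / (sel | det).sum()
        out[k] = (iou, det.sum() * scene.truth_labels.pixel_size ** 2)
    return out


class TestSegmentFas:
    def test_recovers_ground_truth_objects(self, default_scene):
        labels, objs = segment_fas(default_scene.channels["paxillin"])
        assert len(objs) == 12
        matches = _match_truth(default_scene, labels)
        for k, (iou, area) in matches.items():
            assert iou >= 0.7
            truth = default_scene.truth_areas[k]
            assert abs(area - truth) / truth <= 0.10

    def test_out_of_range_objects_are_filtered(self):
        # 0.1 µm² is below and 7 µm² above the default single-FA band
        for area in (0.1, 7.0):
            p = SceneParams(n_objects_inner=1, n_objects_outer=1,
                            area_range=(area * 0.999, area * 1.001),
                            snr=np.inf, seed=5)
            scene = generate_fa_scene(p)
            _, objs = segment_fas(scene.channels["paxillin"])
            assert objs == []

    def test_in_range_objects_are_kept(self):
        p = SceneParams(area_range=(0.25, 5.5), snr=np.inf, seed=6)
        scene = generate_fa_scene(p)
        _, objs = segment_fas(scene.channels["paxillin"])
        assert len(objs) == 12
        for o in objs:
            assert 0.20 < o.area < 6.0

    def test_roundness_definition_and_bounds(self, default_scene):
        _, objs = segment_fas(default_scene.channels["paxillin"])
        for o in objs:
            expected = min(1.0, 4 * o.area / (np.pi * o.major_axis ** 2))
            assert o.roundness == pytest.approx(expected)
            assert 0.0 < o.roundness <= 1.0

    def test_empty_result_is_valid(self):
        # speckle-sized dots (~0.1 µm²) all fall below the area band
        data = np.full((200, 200), 100.0)
        for r, c in [(40, 40), (100, 150), (160, 60)]:
            data[r : r + 3, c : c + 3] = 1000.0
        labels, objs = segment_fas(MicroImage(data, 0.11))
        assert objs == []
        assert labels.n_objects == 0


class TestPartitionRegions:
    def test_disk_fraction_half_gives_half_radius(self):
        shape = (121, 121)
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        dist = np.sqrt((rr - 60) ** 2 + (cc - 60) ** 2)
        cell = dist <= 50
        part = partition_regions(cell, 0.5)
        # differing pixels confined to a 1-px band around radius 25
        analytic = dist <= 25
        mismatch = part.inner_mask ^ analytic
        assert np.all(np.abs(dist[mismatch] - 25) <= 1.5)

    def test_fraction_zero_inner_is_whole_cell(self):
        cell = np.zeros((30, 30), bool)
        cell[5:25, 5:25] = True
        part = partition_regions(cell, 0.0)
        assert np.array_equal(part.inner_mask, cell)
        assert not part.outer_mask.any()

    def test_fraction_one_inner_is_argmax_set(self):
        cell = np.zeros((21, 21), bool)
        cell[3:18, 3:18] = True
        part = partition_regions(cell, 1.0)
        from scipy.ndimage import distance_transform_edt
        edt = distance_transform_edt(cell)
        assert np.array_equal(part.inner_mask, edt == edt.max())

    def test_masks_disjoint_and_exhaustive(self):
        rng = np.random.default_rng(3)
        cell = np.zeros((50, 50), bool)
        cell[10:40, 5:45] = True
        for fraction in (0.2, 0.5, 0.8):
            part = partition_regions(cell, fraction)
            assert not (part.inner_mask & part.outer_mask).any()
            assert np.array_equal(part.inner_mask | part.outer_mask, cell)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValidationError):
            partition_regions(np.zeros((10, 10), bool), 0.5)


class TestClassifyRegion:
    def _obj(self, centroid):
        return FAObject(label=1, area=1.0, centroid=centroid, major_axis=1.0,
                        minor_axis=0.5, roundness=0.8)

    def test_center_of_convex_cell_is_inner(self):
        cell = np.zeros((41, 41), bool)
        cell[5:36, 5:36] = True
        part = partition_regions(cell, 0.5)
        assert classify_region(self._obj((20.0, 20.0)), part) == "inner"

    def test_boundary_is_outer(self):
        cell = np.zeros((41, 41), bool)
        cell[5:36, 5:36] = True
        part = partition_regions(cell, 0.5)
        assert classify_region(self._obj((5.0, 20.0)), part) == "outer"

    def test_outside_cell_raises(self):
        cell = np.zeros((41, 41), bool)
        cell[5:36, 5:36] = True
        part = partition_regions(cell, 0.5)
        with pytest.raises(UnassignedRegionError):
            classify_region(self._obj((0.0, 0.0)), part)

    def test_scene_objects_match_generated_compartment(self, default_scene):
        s = default_scene
        part = partition_regions(s.cell_mask, s.params.region_fraction)
        for k, region in s.truth_regions.items():
            obj = self._obj(s.truth_centroids[k])
            assert classify_region(obj, part) == region


class TestPearsonPerObject:
    def test_identical_channels_give_one(self, default_scene):
        img = default_scene.channels["paxillin"]
        r = pearson_per_object(default_scene.truth_labels, img, img)
        assert all(v == pytest.approx(1.0) for v in r.values())

    def test_inverted_channel_gives_minus_one(self, default_scene):
        img = default_scene.channels["paxillin"]
        inv = img.with_data(img.data.max() - img.data)
        r = pearson_per_object(default_scene.truth_labels, img, inv)
        assert all(v == pytest.approx(-1.0) for v in r.values())

    def test_matches_two_pass_formula_oracle(self, default_scene):
        s = default_scene
        a, b = s.channels["paxillin"], s.channels["septin"]
        r = pearson_per_object(s.truth_labels, a, b)
        for k in s.truth_areas:
            sel = s.truth_labels.labels == k
            av, bv = a.data[sel], b.data[sel]
            num = np.sum((av - av.mean()) * (bv - bv.mean()))
            den = np.sqrt(np.sum((av - av.mean()) ** 2)
                          * np.sum((bv - bv.mean()) ** 2))
            assert abs(r[k] - num / den) < 1e-12

    def test_constant_channel_flagged_nan(self):
        labels = LabelMask(np.array([[1, 1], [1, 0]]), 0.1)
        a = MicroImage(np.array([[1.0, 2.0], [3.0, 0.0]]), 0.1)
        b = MicroImage(np.full((2, 2), 5.0), 0.1)
        r = pearson_per_object(labels, a, b)
        assert np.isnan(r[1])

    def test_geometry_mismatch_rejected(self, default_scene):
        small = MicroImage(np.zeros((10, 10)), 0.11)
        with pytest.raises(ValidationError):
            pearson_per_object(default_scene.truth_labels, small, small)


class TestBinRandom:
    def test_identical_values(self):
        out = bin_random([5.0] * 20, MorphologyConfig(bin_size=10))
        assert np.allclose(out, [5.0, 5.0])

    def test_remainder_dropped(self):
        out = bin_random(np.arange(25.0), MorphologyConfig(bin_size=10))
        assert out.size == 2

    def test_deterministic_given_seed(self):
        vals = np.random.default_rng(1).uniform(0, 1, 40)
        cfg = MorphologyConfig(bin_size=10, seed=99)
        assert np.array_equal(bin_random(vals, cfg), bin_random(vals, cfg))

    def test_fewer_than_bin_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = bin_random([1.0, 2.0], MorphologyConfig(bin_size=10))
        assert out.size == 0

    def test_nan_excluded(self):
        vals = [1.0] * 10 + [np.nan] * 5
        out = bin_random(vals, MorphologyConfig(bin_size=10))
        assert np.allclose(out, [1.0])
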