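import numpy as np
import pytest

from faquant import (FAEvent, PlacementError, SceneParams, ValidationError,
                     generate_clearance_scene, generate_fa_scene,
                     generate_filament_scene, generate_timelapse,
                     generate_tracks, pearson_per_object)


class TestFAScene:
    def test_same_seed_bit_identical(self):
        p = SceneParams(seed=12)
        s1, s2 = generate_fa_scene(p), generate_fa_scene(p)
        for name in s1.channels:
            assert np.array_equal(s1.channels[name].data, s2.channels[name].data)
        assert np.array_equal(s1.truth_labels.labels, s2.truth_labels.labels)

    def test_different_seed_differs(self):
        a = generate_fa_scene(SceneParams(seed=1))
        b = generate_fa_scene(SceneParams(seed=2))
        assert not np.array_equal(a.channels["paxillin"].data,
                                  b.channels["paxillin"].data)

    def test_perfect_copy_limit(self, clean_scene):
        """rho = 1 at infinite SNR makes each object correlate perfectly."""
        r = pearson_per_object(clean_scene.truth_labels,
                               clean_scene.channels["paxillin"],
                               clean_scene.channels["septin"])
        assert all(abs(v - 1.0) < 1e-9 for v in r.values())

    def test_zero_rho_mean_r_near_zero(self):
        """Mean measured r over seeds stays within ±0.05 of 0 for large objects."""
        vals = []
        for seed in range(20):
            p = SceneParams(image_shape=(220, 220), pixel_size=0.1,
                            n_objects_inner=2, n_objects_outer=2,
                            area_range=(5.5, 7.0), rho_inner=0.0,
                            rho_outer=0.0, snr=10.0, seed=seed)
            s = generate_fa_scene(p)
            r = pearson_per_object(s.truth_labels, s.channels["paxillin"],
                                   s.channels["septin"])
            for k, v in r.items():
                if (s.truth_labels.labels == k).sum() >= 500:
                    vals.append(v)
        assert abs(np.mean(vals)) <= 0.05

    def test_objects_confined_to_their_region(self, default_scene):
        s = default_scene
        for k, region in s.truth_regions.items():
            sel = s.truth_labels.labels == k
            mask = s.truth_inner if region == "inner" else s.truth_outer
            assert mask[sel].all()

    def test_every_object_has_truth_entries(self, default_scene):
        s = default_scene
        labels = set(np.unique(s.truth_labels.labels)) - {0}
        assert labels == set(s.truth_rho) == set(s.truth_areas)

    def test_capacity_error(self):
        p = SceneParams(image_shape=(120, 120), n_objects_inner=200,
                        n_objects_outer=0, area_range=(3.0, 4.0))
        with pytest.raises(PlacementError):
            generate_fa_scene(p)

    @pytest.mark.parametrize("kwargs", [
        dict(rho_inner=1.5), dict(snr=0.0), dict(area_range=(4.0, 1.0)),
        dict(pixel_size=-1.0), dict(region_fraction=2.0),
    ])
    def test_param_validation(self, kwargs):
        with pytest.raises(ValidationError):
            SceneParams(**kwargs)


class TestTimelapse:
    def test_lifetime_convention(self):
        tl = generate_timelapse([FAEvent(3, 14, (60, 60))], n_frames=20, dt=10.0)
        ev = tl.truth_events[0]
        assert ev.lifetime_s == 120.0
        assert not ev.censored_start and not ev.censored_end

    def test_censoring_flags(self):
        tl = generate_timelapse([FAEvent(0, 5, (30, 30)),
                                 FAEvent(10, 19, (80, 80))],
                                n_frames=20, dt=10.0)
        assert tl.truth_events[0].censored_start
        assert not tl.truth_events[0].censored_end
        assert tl.truth_events[1].censored_end

    def test_presence_exactly_within_event_frames(self):
        tl = generate_timelapse([FAEvent(2, 6, (40, 40))], n_frames=10, dt=5.0)
        present = (tl.truth_labels == 1).any(axis=(1, 2))
        assert list(np.flatnonzero(present)) == [2, 3, 4, 5, 6]

    def test_empty_events_pure_background(self):
        tl = generate_timelapse([], n_frames=5, dt=10.0, background_level=7.0)
        assert np.all(tl.stack.data == 7.0)
        assert tl.truth_labels.max() == 0

    def test_out_of_range_event_rejected(self):
        with pytest.raises(ValidationError):
            generate_timelapse([FAEvent(0, 30, (10, 10))], n_frames=20, dt=10.0)


class TestClearanceScene:
    def test_truth_arithmetic(self):
        scene = generate_clearance_scene(
            holes=[(10, 10, 20, 10), (100, 100, 20, 10)], n_cells=2,
            pixel_size=0.5, seed=0)
        assert scene.truth_cleared_px == 400
        assert scene.truth_clearance_per_cell_um2 == pytest.approx(200 * 0.25)

    def test_single_hole_example(self):
        scene = generate_clearance_scene(holes=[(50, 50, 10, 10)], n_cells=1,
                                         pixel_size=0.5, seed=1)
        assert scene.truth_clearance_per_cell_um2 == pytest.approx(25.0)

    def test_zero_holes(self):
        scene = generate_clearance_scene(holes=[], n_cells=3, seed=2)
        assert scene.truth_cleared_px == 0
        assert scene.truth_cleared_area_um2 == 0.0

    def test_oversized_hole_rejected(self):
        with pytest.raises(ValidationError):
            generate_clearance_scene(holes=[(0, 0, 500, 500)], n_cells=1,
                                     image_shape=(300, 300))


class TestTracks:
    def test_straight_tracks_are_collinear(self):
        tracks, dets = generate_tracks(3, 50, dt=60.0, step_model="straight",
                                       step_um=2.0, seed=4)
        for trk in tracks:
            steps = np.diff(trk, axis=0)
            assert np.allclose(np.linalg.norm(steps, axis=1), 2.0)
            cross = (steps[:-1, 0] * steps[1:, 1]
                     - steps[:-1, 1] * steps[1:, 0])
            assert np.allclose(cross, 0, atol=1e-9)

    def test_random_walk_net_much_less_than_path(self):
        ratios = []
        for seed in range(20):
            tracks, _ = generate_tracks(1, 2001, dt=60.0,
                                        step_model="random_walk",
                                        step_um=1.0, seed=seed)
            trk = tracks[0]
            path = np.linalg.norm(np.diff(trk, axis=0), axis=1).sum()
            net = np.linalg.norm(trk[-1] - trk[0])
            ratios.append(net / path)
        # E[net] ~ s·sqrt(pi·n)/2 << n·s for a 2D random walk
        assert np.mean(ratios) < 0.05

    def test_zero_tracks_empty_detections(self):
        tracks, dets = generate_tracks(0, 10, dt=1.0, seed=0)
        assert tracks == []
        assert all(d.shape == (0, 2) for d in dets)

    def test_detections_match_truth(self):
        tracks, dets = generate_tracks(2, 5, dt=1.0, step_model="biased_walk",
                                       seed=9)
        for t in range(5):
            truth = np.array([trk[t] for trk in tracks])
            assert np.allclose(np.sort(dets[t], axis=0), np.sort(truth, axis=0))


class TestFilamentScene:
    def test_deterministic(self):
        a = generate_filament_scene(seed=3)
        b = generate_filament_scene(seed=3)
        assert np.array_equal(a.data, b.data)

    def test_invalid_fraction(self):
        with pytest.raises(ValidationError):
            generate_filament_scene(aligned_fraction=1.5)
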