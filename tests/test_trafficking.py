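"""Trafficking pipeline: background removal, detection, linking, filtering."""

import itertools
import math

import numpy as np
import pytest

from timescope import (Detection, Tracklet, TraffickingThresholds, VideoStack,
                       compute_tracklet_features, count_trafficking,
                       detect_spots, filter_tracklets, generate_rcm_video,
                       link_detections, px_to_um, px_to_um_display,
                       subtract_background)

ALT_COST = (1.05 * 20.0) ** 2


def gaussian_blob(shape, x, y, sigma, amplitude):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return amplitude * np.exp(-((yy - y) ** 2 + (xx - x) ** 2)
                              / (2 * sigma ** 2))


class TestBackgroundSubtraction:
    def test_constant_video_becomes_zero(self):
        video = VideoStack(frames=np.full((40, 32, 32), 0.8))
        out = subtract_background(video)
        assert np.abs(out.frames).max() == 0.0

    def test_transient_preserved_static_removed(self):
        rng = np.random.default_rng(0)
        texture = rng.uniform(0.2, 0.8, size=(48, 48))
        frames = np.tile(texture, (40, 1, 1))
        amplitude = 2.0
        frames[20] += gaussian_blob((48, 48), 24, 24, 4.0, amplitude)
        out = subtract_background(VideoStack(frames=frames)).frames
        assert out[20, 24, 24] >= 0.9 * amplitude
        static = np.delete(out, 20, axis=0)
        assert np.abs(static).max() <= 0.01 * amplitude

    def test_boundary_window_truncated(self):
        # per-pixel ramp in time: frame 0's background is the median of the
        # first 16 frames (half-window 15 + itself), i.e. 7.5
        frames = np.ones((40, 20, 20)) * np.arange(40)[:, None, None]
        out = subtract_background(VideoStack(frames=frames)).frames
        assert out[0, 0, 0] == pytest.approx(0.0 - 7.5)

    def test_window_too_short_rejected(self):
        video = VideoStack(frames=np.zeros((10, 20, 20)), frame_interval_s=4.0)
        with pytest.raises(ValueError, match="window"):
            subtract_background(video, window_s=6.0)


class TestDetectSpots:
    def test_blank_frame_has_no_detections(self):
        assert detect_spots(np.zeros((64, 64))) == []

    def test_single_blob_localized_subpixel(self):
        sigma = 7.5 / math.sqrt(2)
        frame = gaussian_blob((96, 96), 47.6, 52.3, sigma, 2.0)
        dets = detect_spots(frame)
        assert len(dets) == 1
        assert math.hypot(dets[0].x - 47.6, dets[0].y - 52.3) < 0.5
        # quality is normalized to the blob amplitude scale
        assert dets[0].quality == pytest.approx(2.0, abs=0.1)

    def test_two_blobs_thirty_px_apart(self):
        sigma = 7.5 / math.sqrt(2)
        frame = (gaussian_blob((96, 96), 30, 48, sigma, 2.0)
                 + gaussian_blob((96, 96), 60, 48, sigma, 2.0))
        assert len(detect_spots(frame)) == 2

    def test_subthreshold_blob_ignored(self):
        sigma = 7.5 / math.sqrt(2)
        frame = gaussian_blob((96, 96), 48, 48, sigma, 1.0)
        assert detect_spots(frame, quality_threshold=1.6) == []


def brute_force_pair_cost(points_a, points_b, max_link=20.0):
    """Minimum cost over all partial matchings of one frame pair."""
    n, m = len(points_a), len(points_b)
    best = math.inf
    for k in range(min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = sum((a - b) ** 2
                             for a, b in zip(points_a[i], points_b[j]))
                    if d2 > max_link ** 2:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += ALT_COST * (n - k) + ALT_COST * (m - k)
                best = min(best, cost)
    return best


def achieved_pair_costs(tracklets, detections_by_frame):
    """Per-frame-pair linking cost implied by the returned tracklets."""
    links = {}  # frame -> list of (prev xy, cur xy)
    for t in tracklets:
        for a, b in zip(t.detections, t.detections[1:]):
            links.setdefault(b.frame_index, []).append(
                ((a.x, a.y), (b.x, b.y)))
    costs = []
    for f in range(1, len(detections_by_frame)):
        n = len(detections_by_frame[f - 1])
        m = len(detections_by_frame[f])
        pair_links = links.get(f, [])
        cost = sum((ax - bx) ** 2 + (ay - by) ** 2
                   for (ax, ay), (bx, by) in pair_links)
        cost += ALT_COST * (n - len(pair_links))
        cost += ALT_COST * (m - len(pair_links))
        costs.append(cost)
    return costs


class TestLinking:
    def test_single_moving_spot_one_tracklet(self):
        dets = [[Detection(0, 10.0 + 5 * t, 20.0, 2.0)] for t in range(10)]
        tracklets = link_detections(dets)
        assert len(tracklets) == 1
        assert len(tracklets[0]) == 10

    def test_jump_beyond_max_distance_splits(self):
        # 25 px > the 20 px max match distance
        dets = [[Detection(0, 10.0, 10.0, 2.0)],
                [Detection(0, 35.0, 10.0, 2.0)],
                [Detection(0, 40.0, 10.0, 2.0)]]
        tracklets = link_detections(dets)
        assert all(len(t) < 3 for t in tracklets)
        assert len(tracklets) == 1  # frames 1-2 link (5 px); frame 0 orphaned

    @pytest.mark.parametrize("seed", range(8))
    def test_linking_matches_brute_force_assignment(self, seed):
        rng = np.random.default_rng(seed)
        dets = []
        for f in range(4):
            pts = rng.uniform(0, 60, size=(rng.integers(0, 5), 2))
            dets.append([Detection(0, float(x), float(y), 2.0)
                         for x, y in pts])
        tracklets = link_detections(dets)
        achieved = achieved_pair_costs(tracklets, dets)
        for f in range(1, 4):
            pa = [(d.x, d.y) for d in dets[f - 1]]
            pb = [(d.x, d.y) for d in dets[f]]
            assert achieved[f - 1] == pytest.approx(
                brute_force_pair_cost(pa, pb), rel=1e-9)

    def test_no_link_exceeds_max_distance(self, trafficking_video):
        video, _ = trafficking_video
        _, tracklets = count_trafficking(video)
        for t in tracklets:
            steps = np.linalg.norm(np.diff(t.positions, axis=0), axis=1)
            assert (steps <= 20.0).all()


class TestTrackletFeatures:
    def test_collinear_steps_zero_consistency(self):
        t = Tracklet([Detection(i, 10.0 + 6 * i, 5.0, 2.0) for i in range(5)])
        disp_px, disp_um, dur, cons, qual = compute_tracklet_features(t)
        assert cons == 0.0
        assert disp_px == pytest.approx(24.0)
        assert disp_um == pytest.approx(24.0 / 1.33)
        assert dur == pytest.approx(1.0)  # 5 detections at 0.2 s

    def test_right_angle_zigzag_is_ninety_degrees(self):
        pts = [(0, 0), (5, 0), (5, 5), (10, 5), (10, 10)]
        t = Tracklet([Detection(i, float(x), float(y), 2.0)
                      for i, (x, y) in enumerate(pts)])
        assert compute_tracklet_features(t)[3] == pytest.approx(90.0)

    def test_zero_length_steps_skipped(self):
        pts = [(0, 0), (5, 0), (5, 0), (10, 0)]
        t = Tracklet([Detection(i, float(x), float(y), 2.0)
                      for i, (x, y) in enumerate(pts)])
        assert compute_tracklet_features(t)[3] == 0.0

    def test_all_zero_steps_consistency_zero(self):
        t = Tracklet([Detection(i, 5.0, 5.0, 2.0) for i in range(4)])
        assert compute_tracklet_features(t)[3] == 0.0

    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="consecutive"):
            Tracklet([Detection(0, 0.0, 0.0, 1.0),
                      Detection(2, 5.0, 0.0, 1.0)])


class TestFiltering:
    def worked_track(self, quality=2.0):
        """5-frame straight track with 6-px steps: 24 px displacement."""
        return Tracklet([Detection(i, 10.0 + 6 * i, 5.0, quality)
                         for i in range(5)])

    def test_worked_example_kept_for_window_zero(self):
        kept = filter_tracklets([self.worked_track()], window_index=0)
        assert len(kept) == 1

    def test_low_displacement_jitter_discarded_everywhere(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.normal(0, 0.4, size=(8, 2)), axis=0)
        t = Tracklet([Detection(i, float(x + 50), float(y + 50), 2.0)
                      for i, (x, y) in enumerate(pts)])
        disp = compute_tracklet_features(t)[0]
        assert disp < 20.5
        for w in range(3):
            assert filter_tracklets([t], window_index=w) == []

    def test_printed_threshold_arrays(self):
        th = TraffickingThresholds()
        assert th.displacement_px == (20.5, 22.5, 22.5)
        assert th.consistency_deg == (58.0, 58.0, 58.0)
        assert th.quality == (1.6, 1.65, 1.75)
        assert th.windows_s == (0.6, 0.8, 1.0)
        # window 1: 22.5 px, 58 deg, 1.65, 0.8 s
        assert (th.displacement_px[1], th.consistency_deg[1],
                th.quality[1], th.windows_s[1]) == (22.5, 58.0, 1.65, 0.8)

    def test_displacement_um_consistent_with_px(self):
        th = TraffickingThresholds()
        for px, um in zip(th.displacement_px, th.displacement_um):
            assert abs(px / 1.33 - um) < 0.01

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            filter_tracklets([self.worked_track()], window_index=3)

    def test_filtering_monotone_in_each_threshold(self):
        tracks = [self.worked_track(quality=q) for q in (1.7, 1.9, 2.2)]
        base = len(filter_tracklets(tracks, window_index=0))
        stricter = TraffickingThresholds(
            displacement_px=(25.0, 25.0, 25.0),
            quality=(2.0, 2.0, 2.0),
            consistency_deg=(30.0, 30.0, 30.0))
        assert len(filter_tracklets(tracks, stricter, 0)) <= base


class TestEndToEnd:
    def test_static_video_counts_zero(self, static_video):
        counts, _ = count_trafficking(static_video)
        assert counts == (0, 0, 0)

    def test_planted_cells_recovered(self, trafficking_video):
        video, truth = trafficking_video
        counts, _ = count_trafficking(video)
        k = len(truth.particle_tracks)
        assert abs(counts[0] - k) <= 1

    def test_counts_monotone_across_windows(self, trafficking_video):
        video, _ = trafficking_video
        counts, _ = count_trafficking(video)
        assert counts[0] >= counts[1] >= counts[2]


class TestUnitConversion:
    def test_printed_conversions(self):
        assert px_to_um_display(7.5) == 5.63
        assert px_to_um_display(20.0) == 15.03
        assert px_to_um_display(20.5) == 15.41

    def test_zero(self):
        assert px_to_um(0.0) == 0.0

    def test_exact_quotient(self):
        assert px_to_um(7.5) == pytest.approx(7.5 / 1.33)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            px_to_um(1.0, pixel_per_um=0.0)
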