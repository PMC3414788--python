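"""Focal-adhesion segmentation, tracking, filtering and summaries."""

import numpy as np
import pytest

import famotion as fm
from famotion.adhesions import FATrack, analyze_fa_movie, segment_cell, segment_fas

from conftest import render_spot

PX = 0.16


class TestSegmentCell:
    def test_uniform_frame_gives_empty_mask(self):
        with pytest.warns(UserWarning):
            mask = segment_cell(np.full((64, 64), 5.0), PX)
        assert not mask.any()

    def test_noisy_uniform_frame_gives_empty_mask(self, rng):
        with pytest.warns(UserWarning):
            mask = segment_cell(400 + rng.normal(0, 30, (128, 128)), PX)
        assert not mask.any()

    def test_disk_area_within_2_percent(self):
        H = W = 192
        yy, xx = np.mgrid[0:H, 0:W]
        disk = (np.hypot(yy - 96, xx - 96) * PX) <= 10.0
        frame = 100.0 + 500.0 * disk
        mask = segment_cell(frame, PX)
        assert abs(mask.sum() - disk.sum()) / disk.sum() < 0.02

    def test_scale_invariance(self):
        H = W = 160
        yy, xx = np.mgrid[0:H, 0:W]
        frame = 100.0 + 500.0 * ((np.hypot(yy - 80, xx - 80) * PX) <= 8.0)
        m1 = segment_cell(frame, PX)
        m2 = segment_cell(frame * 7.3, PX)
        assert np.array_equal(m1, m2)


class TestSegmentFAs:
    def test_blank_frame_zero_components(self):
        labels = segment_fas(np.full((96, 96), 400.0), np.ones((96, 96), bool), PX)
        assert labels.max() == 0

    def test_five_separated_spots_recovered(self):
        H = W = 256
        frame = np.full((H, W), 400.0)
        centers = [(50, 60), (190, 60), (120, 128), (60, 200), (200, 196)]
        for cx, cy in centers:
            frame += render_spot((H, W), (cx, cy), 1.2, 1.6, 8000.0, PX,
                                 background=0.0)
        labels = segment_fas(frame, np.ones((H, W), bool), PX)
        assert labels.max() == 5
        from skimage.measure import regionprops
        rec = sorted((r.centroid[1], r.centroid[0]) for r in regionprops(labels))
        for (rx, ry), (cx, cy) in zip(rec, sorted(centers)):
            assert abs(rx - cx) < 0.5 and abs(ry - cy) < 0.5

    def test_two_pixel_spot_removed(self):
        # sub-resolution object: 2 hot pixels -> excluded by the 3-px rule
        frame = np.full((96, 96), 400.0)
        frame[48, 48:50] = 8000.0
        labels = segment_fas(frame, np.ones((96, 96), bool), PX)
        assert labels.max() == 0

    def test_area_matches_halfmax_convention(self):
        frame = render_spot((128, 128), (64.3, 63.7), 1.5, 2.0, 8000.0, PX)
        labels = segment_fas(frame, np.ones((128, 128), bool), PX)
        assert labels.max() == 1
        from famotion.adhesions import SIZING_SIGMA_PX, _measure
        props = _measure(labels, None, SIZING_SIGMA_PX)
        # single static frame: pixelation phase leaves a few-percent residual
        assert props[1]["area"] * PX**2 == pytest.approx(1.5, rel=0.10)
        assert props[1]["elongation"] == pytest.approx(2.0, rel=0.08)


def single_spot_label_stack(n_frames, center_fn, area=1.2, peak=8000.0,
                            shape=(128, 128)):
    movie = []
    for t in range(n_frames):
        movie.append(render_spot(shape, center_fn(t), area, 1.5, peak, PX))
    labels = [segment_fas(f, np.ones(shape, bool), PX) for f in movie]
    return movie, labels


class TestTrackFAs:
    def test_single_stationary_fa(self):
        _, labels = single_spot_label_stack(6, lambda t: (64.0, 64.0))
        tracks = fm.track_fas(labels, 10.0, PX)
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.first_frame == 0 and tr.last_frame == 5
        assert tr.censored_start and tr.censored_end

    def test_gap_closing_spans_one_missing_frame(self):
        _, labels = single_spot_label_stack(7, lambda t: (64.0, 64.0))
        labels[3] = np.zeros_like(labels[3])  # FA invisible for one frame
        tracks = fm.track_fas(labels, 10.0, PX, gap_frames=1)
        assert len(tracks) == 1
        assert list(tracks[0].frames) == list(range(7))
        assert np.isnan(tracks[0].areas[3])  # gap frame carries no measurement

    def test_no_identity_swap_for_distant_crossing(self):
        # two FAs pass at closest distance > per-frame displacement limit
        shape = (160, 160)
        frames, labels = [], []
        for t in range(9):
            f = render_spot(shape, (40 + 10 * t, 70.0), 1.2, 1.5, 9000.0, PX)
            f += render_spot(shape, (120 - 10 * t, 90.0), 1.2, 1.5, 9000.0, PX,
                             background=0.0)
            labels.append(segment_fas(f, np.ones(shape, bool), PX))
        tracks = fm.track_fas(labels, 10.0, PX, max_disp_um=2.0)
        assert len(tracks) == 2
        for tr in tracks:
            dy = np.diff(tr.centroids[:, 1])
            assert np.all(np.abs(dy) < 1.0)  # each track keeps its own row

    def test_mask_shape_mismatch(self):
        with pytest.raises(ValueError, match="frame 1"):
            fm.track_fas([np.zeros((4, 4), int), np.zeros((5, 5), int)], 10.0, PX)


class TestFilterFAs:
    @staticmethod
    def track_with_area(area):
        n = 3
        return FATrack(fa_id=1, frames=np.arange(n),
                       centroids=np.zeros((n, 2)), areas=np.full(n, area),
                       mean_intensities=np.ones(n),
                       integrated_intensities=np.ones(n),
                       elongations=np.ones(n))

    def test_boundary_inclusive_bounds(self):
        tracks = [self.track_with_area(a) for a in (0.04, 0.05, 5.0, 10.0, 12.0)]
        kept = fm.filter_fas(tracks)
        assert sorted(t.mean_area() for t in kept) == pytest.approx([0.05, 5.0, 10.0])

    def test_empty_input(self):
        assert fm.filter_fas([]) == []

    def test_idempotence(self, rng):
        tracks = [self.track_with_area(a) for a in rng.lognormal(0, 1, 50)]
        once = fm.filter_fas(tracks)
        assert fm.filter_fas(once) == once

    def test_tightening_bounds_monotone(self, rng):
        areas = rng.lognormal(0, 1.5, 100)
        tracks = [self.track_with_area(a) for a in areas]
        prev = len(fm.filter_fas(tracks, 0.01, 50.0))
        for lo, hi in [(0.05, 10.0), (0.1, 5.0), (0.5, 2.0)]:
            kept = len(fm.filter_fas(tracks, lo, hi))
            oracle = int(np.sum((areas >= lo) & (areas <= hi)))
            assert kept == oracle
            assert kept <= prev
            prev = kept

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            fm.filter_fas([], min_area=5.0, max_area=1.0)


class TestSummaries:
    @staticmethod
    def moving_track(n, step_um, frame0=0):
        xs = np.arange(n) * step_um
        return FATrack(fa_id=1, frames=np.arange(frame0, frame0 + n),
                       centroids=np.column_stack([xs, np.zeros(n)]),
                       areas=np.ones(n), mean_intensities=np.ones(n),
                       integrated_intensities=np.ones(n),
                       elongations=np.ones(n))

    def test_lifetime_inclusive_convention(self):
        tr = self.moving_track(8, 0.0, frame0=3)  # frames 3..10
        assert tr.lifetime_s(10.0) == 80.0

    def test_stationary_sliding_speed_zero(self):
        assert self.moving_track(10, 0.0).sliding_speed_um_hr(10.0) == 0.0

    def test_sliding_speed_unit_conversion(self):
        # 0.1 um per 10-s frame = 36 um/hr
        tr = self.moving_track(12, 0.1)
        assert tr.sliding_speed_um_hr(10.0) == pytest.approx(36.0, rel=1e-9)

    def test_single_frame_speed_missing(self):
        tr = self.moving_track(1, 0.0)
        summary = fm.summarize_fa_properties([tr], 10.0)
        assert np.isnan(summary["slide_um_per_hr"].iloc[0])

    def test_censored_flags_in_table(self):
        tr = self.moving_track(5, 0.1, frame0=0)
        tr.censored_start = True
        summary = fm.summarize_fa_properties([tr], 10.0)
        assert bool(summary["censored_start"].iloc[0])
        assert bool(summary["censored"].iloc[0])


class TestFANumberPerCell:
    def test_empty_masks_zero_counts(self):
        assert np.all(fm.fa_number_per_cell([], 7) == 0)

    def test_counts_match_ground_truth(self, small_fa_movie):
        params, movie, truth = small_fa_movie
        result = analyze_fa_movie(movie)
        gt_counts = fm.fa_number_per_cell(truth, movie.n_frames)
        np.testing.assert_array_equal(result["counts"], gt_counts)

    def test_filtering_bookkeeping(self, small_fa_movie):
        params, movie, truth = small_fa_movie
        result = analyze_fa_movie(movie)
        before = fm.fa_number_per_cell(result["all_tracks"], movie.n_frames)
        after = fm.fa_number_per_cell(result["tracks"], movie.n_frames)
        removed = [t for t in result["all_tracks"] if t not in result["tracks"]]
        removed_live = fm.fa_number_per_cell(removed, movie.n_frames)
        np.testing.assert_array_equal(before - after, removed_live)


class TestQCIntensityDrift:
    def test_constant_movie_not_flagged(self):
        frames = np.full((12, 32, 32), 500.0)
        movie = fm.FAMovie(frames, PX, 10.0)
        masks = [np.ones((32, 32), bool)] * 12
        slope, loss, flagged = fm.qc_intensity_drift(movie, masks)
        assert slope == pytest.approx(0.0, abs=1e-9)
        assert not flagged

    def test_bleaching_movie_flagged_with_matching_sign(self):
        params = fm.FAMovieParams(n_frames=30, birth_rate=0.4, noise_sd=10.0,
                                  bleach_rate=0.008, seed=3,
                                  frame_shape=(160, 160))
        movie, _ = fm.simulate_fa_movie(params)
        masks = [segment_cell(f.astype(float), PX) for f in movie.frames]
        slope, loss, flagged = fm.qc_intensity_drift(movie, masks)
        assert slope < 0  # sign matches the imposed decay
        assert flagged  # (1-0.008)^30 ~ 21% loss > 10% tolerance

    def test_errors(self):
        movie = fm.FAMovie(np.full((12, 8, 8), 5.0), PX, 10.0)
        with pytest.raises(ValueError, match="mask"):
            fm.qc_intensity_drift(movie, [np.zeros((8, 8), bool)] * 12)
        short = fm.FAMovie(np.full((4, 8, 8), 5.0), PX, 10.0)
        with pytest.raises(ValueError, match="10 frames"):
            fm.qc_intensity_drift(short, [np.ones((8, 8), bool)] * 4)


class TestEndToEndRecovery:
    def test_noise_free_counts_exact_and_areas_analytic(self, small_fa_movie):
        params, movie, truth = small_fa_movie
        result = analyze_fa_movie(movie)
        gt_counts = fm.fa_number_per_cell(truth, movie.n_frames)
        np.testing.assert_array_equal(result["counts"], gt_counts)
        # time-averaged areas close to the analytic half-maximum value
        gt_areas = np.sort([t.mean_area() for t in truth])
        rec_areas = np.sort(result["summary"]["area_um2"].to_numpy())
        assert rec_areas.size == gt_areas.size
        px2 = movie.pixel_size**2
        assert np.all(np.abs(rec_areas - gt_areas) < 1.5 * px2 + 0.05 * gt_areas)

    def test_tracking_identity_one_to_one(self, small_fa_movie):
        params, movie, truth = small_fa_movie
        result = analyze_fa_movie(movie)
        assert len(result["tracks"]) == len(truth)
        # match every recovered track to a distinct ground-truth FA
        used = set()
        for rt in result["tracks"]:
            match = None
            for gt in truth:
                if gt.fa_id in used:
                    continue
                common = np.intersect1d(rt.frames, gt.frames)
                if common.size == 0:
                    continue
                ir = np.searchsorted(rt.frames, common)
                ig = np.searchsorted(gt.frames, common)
                if np.mean(np.linalg.norm(rt.centroids[ir] - gt.centroids[ig],
                                          axis=1)) < 0.5:
                    match = gt.fa_id
                    break
            assert match is not None
            used.add(match)
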