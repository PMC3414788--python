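"""Synthetic-data generators: determinism, limits, distributional fidelity."""

import dataclasses

import numpy as np
import pytest

import famotion as fm
from famotion.simulate import (DEFAULT_CONDITIONS, dist_cdf, sample_dist)


class TestPRWTracks:
    def test_zero_speed_stays_at_origin(self):
        tracks = fm.simulate_prw_tracks(fm.PRWParams(speed=0.0, n_cells=3, seed=1))
        for tr in tracks:
            assert np.all(tr.positions == 0.0)

    def test_seed_determinism(self):
        p = fm.PRWParams(speed=35, persistence=0.15, n_cells=4, seed=7)
        a = fm.simulate_prw_tracks(p)
        b = fm.simulate_prw_tracks(p)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.positions, tb.positions)

    def test_ensemble_msd_matches_prw_law(self):
        # S=40 um/hr, P=0.2 hr, dt=2 min, 8 hr, 200 cells: each lag <= 30 min
        # within 3 standard errors of the closed form
        p = fm.PRWParams(speed=40, persistence=0.2, dt=2.0, duration=480.0,
                         n_cells=200, seed=2)
        tracks = fm.simulate_prw_tracks(p)
        curves = np.array([fm.compute_msd(t, max_lag=30).msd for t in tracks])
        lags = fm.compute_msd(tracks[0], max_lag=30).lags
        expected = fm.prw_msd(lags, 40 / 60.0, 0.2 * 60.0)
        mean = curves.mean(axis=0)
        sem = curves.std(axis=0, ddof=1) / np.sqrt(len(tracks))
        assert np.all(np.abs(mean - expected) < 3.0 * sem + 1e-9)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            fm.PRWParams(persistence=0.0)
        with pytest.raises(ValueError):
            fm.PRWParams(dt=-1.0)
        with pytest.raises(ValueError):
            fm.PRWParams(duration=1.0, dt=2.0)


@pytest.mark.parametrize("spec", [
    ("lognormal", {"mean_log": 0.0, "sigma_log": 0.5}),
    ("weibull", {"shape": 1.5, "scale": 10.0}),
    ("gaussian", {"mean": 3.0, "sd": 0.7}),
    ("exponential", {"mean": 300.0}),
    ("uniform", {"low": 1.0, "high": 2.0}),
])
def test_distributional_self_consistency(spec):
    # n=5000 ground-truth draws lie within KS 0.03 of the configured family
    rng = np.random.default_rng(99)
    x = sample_dist(rng, spec, 5000)
    assert fm.one_sample_ks(x, lambda v: dist_cdf(spec, v)) < 0.03


class TestFAMovie:
    def test_no_births_gives_background_only(self):
        p = fm.FAMovieParams(n_frames=5, birth_rate=0.0, noise_sd=0.0,
                             frame_shape=(64, 64), seed=1)
        movie, truth = fm.simulate_fa_movie(p)
        assert truth == []
        inner = movie.frames[:, 28:36, 28:36]
        assert np.all(inner == inner[0, 0, 0])  # cell plateau, no spots

    def test_seed_determinism(self):
        p = fm.FAMovieParams(n_frames=8, birth_rate=0.5, seed=3,
                             frame_shape=(96, 96))
        m1, t1 = fm.simulate_fa_movie(p)
        m2, t2 = fm.simulate_fa_movie(p)
        np.testing.assert_array_equal(m1.frames, m2.frames)
        assert len(t1) == len(t2)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.centroids, b.centroids)

    def test_ground_truth_areas_follow_configured_distribution(self):
        # enough births for ~500 adhesions
        p = fm.FAMovieParams(n_frames=60, birth_rate=9.0, noise_sd=0.0,
                             frame_shape=(64, 64), seed=4,
                             lifetime_dist=("constant", {"value": 40.0}))
        _, truth = fm.simulate_fa_movie(p)
        assert len(truth) >= 500
        areas = np.array([t.areas[0] for t in truth])
        d = fm.one_sample_ks(areas, lambda v: dist_cdf(p.area_dist, v))
        assert d < 0.08

    def test_overlap_warning_recorded(self):
        p = fm.FAMovieParams(n_frames=10, birth_rate=20.0, seed=1,
                             frame_shape=(96, 96))
        movie, _ = fm.simulate_fa_movie(p)
        assert any("overlap" in w for w in movie.metadata["warnings"])

    def test_bleaching_decays_ground_truth_intensity(self):
        p = fm.FAMovieParams(n_frames=30, birth_rate=0.0, bleach_rate=0.01,
                             seed=1, frame_shape=(64, 64))
        assert p.bleach_rate == 0.01  # parameter accepted; decay per frame
        p2 = fm.FAMovieParams(n_frames=30, birth_rate=2.0, bleach_rate=0.02,
                              seed=6, frame_shape=(96, 96),
                              intensity_profile="flat",
                              lifetime_dist=("constant", {"value": 300.0}))
        _, truth = fm.simulate_fa_movie(p2)
        tr = max(truth, key=lambda t: t.n_frames)
        ratios = tr.mean_intensities[1:] / tr.mean_intensities[:-1]
        np.testing.assert_allclose(ratios, 0.98, rtol=1e-9)


class TestEdgeMovie:
    def test_static_disk_has_zero_velocities(self):
        p = fm.EdgeSimParams(mode="random", noise_sd=0.0, n_frames=5, seed=1)
        masks, gt, info = fm.simulate_edge_movie(p)
        assert np.all(gt.velocities == 0.0)
        assert all(np.array_equal(m, masks[0]) for m in masks)

    def test_wave_ground_truth_has_diagonal_stripes(self):
        p = fm.EdgeSimParams(mode="wave", wave_amplitude=1.5, noise_sd=0.0,
                             n_frames=30, seed=2)
        masks, gt, info = fm.simulate_edge_movie(p)
        v_lat = info["lateral_speed_sectors_per_frame"]
        v = gt.velocities
        # shifting by the lateral speed per frame reproduces the pattern
        shift = int(round(v_lat * 4))
        np.testing.assert_allclose(
            np.roll(v, -shift, axis=0)[:, 4:], v[:, :-4], atol=1e-6 + 0.05 * np.abs(v).max())

    def test_seed_determinism(self):
        p = fm.EdgeSimParams(mode="random", noise_sd=0.4, n_frames=6, seed=9)
        m1, g1, _ = fm.simulate_edge_movie(p)
        m2, g2, _ = fm.simulate_edge_movie(p)
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(g1.velocities, g2.velocities)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError, match="amplitude"):
            fm.EdgeSimParams(mode="wave", wave_amplitude=20.0, base_radius=15.0)
        with pytest.raises(ValueError, match="lateral"):
            fm.EdgeSimParams(mode="wave", wave_amplitude=1.0,
                             wave_lateral_speed=0.0)
        with pytest.raises(ValueError, match="mode"):
            fm.EdgeSimParams(mode="spiral")


class TestConditionDataset:
    @staticmethod
    def tiny_map(**kwargs):
        return fm.ConditionMap(
            n_cells_per_dose=4, n_fa_movies_per_dose=1, n_edge_movies_per_dose=1,
            fa=fm.FAMovieParams(n_frames=12, frame_shape=(96, 96)),
            edge=fm.EdgeSimParams(noise_sd=0.25, n_frames=12),
            **kwargs)

    def test_dose_outside_panel_rejected(self):
        with pytest.raises(ValueError, match="panel"):
            fm.ConditionMap(conditions={0.0: fm.ConditionOverrides(),
                                        0.5: fm.ConditionOverrides()})

    def test_fewer_than_two_doses_rejected(self):
        with pytest.raises(ValueError, match="two"):
            fm.ConditionMap(conditions={0.0: fm.ConditionOverrides()})

    def test_imposed_intensity_ordering_recovered_in_ground_truth(self):
        bundle = fm.make_condition_dataset(self.tiny_map(), seed=5)
        means = {}
        for dose, data in bundle.items():
            vals = [t.mean_intensity() for fmv in data["fa_movies"]
                    for t in fmv["truth"]]
            means[dose] = np.mean(vals)
        group = {"no": means[0.0],
                 "low": np.mean([means[0.01], means[0.1]]),
                 "high": np.mean([means[1.0], means[10.0], means[100.0]])}
        assert group["no"] > group["low"] > group["high"]

    def test_null_map_gives_small_pairwise_ks(self):
        base = fm.ConditionOverrides()
        cmap = self.tiny_map(conditions={d: base for d in DEFAULT_CONDITIONS})
        bundle = fm.make_condition_dataset(cmap, seed=6)
        groups = {"no": [], "low": [], "high": []}
        for dose, data in bundle.items():
            label = fm.egf_group_label(dose)
            for fmv in data["fa_movies"]:
                groups[label] += [t.mean_area() for t in fmv["truth"]]
        d = fm.mean_pairwise_ks({k: np.array(v) for k, v in groups.items()})
        assert d < 0.25  # sampling noise only at these sizes

    def test_determinism(self):
        b1 = fm.make_condition_dataset(self.tiny_map(), seed=3)
        b2 = fm.make_condition_dataset(self.tiny_map(), seed=3)
        np.testing.assert_array_equal(
            b1[0.0]["fa_movies"][0]["movie"].frames,
            b2[0.0]["fa_movies"][0]["movie"].frames)
        np.testing.assert_array_equal(
            b1[10.0]["trajectories"][2].positions,
            b2[10.0]["trajectories"][2].positions)
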