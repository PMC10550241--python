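"""MSD statistics, anomalous-diffusion fitting and mask conditioning."""

import numpy as np
import pytest

from ptmtrack.errors import (EmptyEnsembleError, FitDomainError,
                             ParameterError)
from ptmtrack.masks import MaskSeries
from ptmtrack.spt import (MSDCurve, _alpha_from_curves,
                          assign_tracks_to_masks, compare_real_vs_random,
                          ea_ta_msd, estimate_localization_offset,
                          fit_anomalous, localization_sigma, resampled_alpha,
                          resampled_alpha_datasets, segments_with_label,
                          ta_msd)
from ptmtrack.synthetic import (add_localization_noise, generate_fbm_tracks,
                                generate_scene, SceneConfig)
from ptmtrack.tracks import Trajectory, TrajectorySet

DT = 0.0867


def brute_force_ta_msd(track, max_lag):
    """Independent double-loop evaluation of the time-averaged MSD."""
    pos = track.positions
    n_pts = len(track)
    out = []
    for n in range(1, max_lag + 1):
        acc = 0.0
        for j in range(n_pts - n):
            d = pos[j + n] - pos[j]
            acc += d @ d
        out.append(acc / (n_pts - n))
    return np.array(out)


class TestTaMsd:
    def test_stationary_track_zero(self):
        tr = Trajectory(0, np.arange(6), np.ones(6), np.ones(6))
        assert np.all(ta_msd(tr).values == 0)

    def test_ballistic_closed_form(self):
        tr = Trajectory(0, np.arange(4), np.arange(4.0), np.zeros(4))
        assert ta_msd(tr).values.tolist() == [1.0, 4.0, 9.0]

    def test_matches_brute_force(self, rng):
        for i in range(100):
            n = rng.integers(5, 15)
            tr = Trajectory(i, np.arange(n), rng.normal(size=n),
                            rng.normal(size=n))
            fast = ta_msd(tr).values
            slow = brute_force_ta_msd(tr, n - 1)
            assert np.max(np.abs(fast - slow)) < 1e-12

    def test_overlong_lag_trimmed(self):
        tr = Trajectory(0, np.arange(5), np.arange(5.0), np.zeros(5))
        assert ta_msd(tr, max_lag=50).values.size == 4


class TestEaTaMsd:
    def test_identical_tracks_zero_sem(self):
        tr = Trajectory(0, np.arange(8), np.arange(8.0), np.zeros(8))
        curve = ea_ta_msd([tr, tr], DT, truncate=None)
        assert np.all(curve.sem == 0)
        assert np.array_equal(curve.values, ta_msd(tr).values)

    def test_single_track_equals_itself(self):
        tr = Trajectory(0, np.arange(8), np.arange(8.0), np.zeros(8))
        curve = ea_ta_msd([tr], DT, truncate=None)
        assert np.array_equal(curve.values, ta_msd(tr).values)

    def test_fbm_ensemble_matches_power_law(self):
        tracks = generate_fbm_tracks(1000, 11, DT, 0.03, 0.5, seed=1)
        curve = ea_ta_msd(tracks, DT, truncate=10)
        expected = 0.03 * curve.lags[:5] ** 0.5
        assert np.all(np.abs(curve.values[:5] / expected - 1) < 0.05)

    def test_empty_ensemble_raises(self):
        with pytest.raises(EmptyEnsembleError):
            ea_ta_msd([], DT)


class TestOffsetAndFit:
    def test_two_point_exact_for_linear_msd(self):
        lags = DT * np.arange(1, 10)
        curve = MSDCurve(lags, 0.05 * lags + 0.0036)
        off = estimate_localization_offset(curve, "two_point")
        assert off == pytest.approx(0.0036)
        assert localization_sigma(off) == pytest.approx(0.03)

    def test_two_point_floor_at_zero(self):
        lags = DT * np.arange(1, 5)
        curve = MSDCurve(lags, np.array([1.0, 3.0, 5.0, 7.0]))
        assert estimate_localization_offset(curve, "two_point") == 0.0

    def test_power_law_offset_recovers_sigma(self):
        lags = DT * np.arange(1, 10)
        curve = MSDCurve(lags, 0.03 * lags ** 0.5 + 0.0036)
        off = estimate_localization_offset(curve, "power_law")
        assert localization_sigma(off) == pytest.approx(0.03, rel=0.10)

    def test_exact_power_law_fit(self):
        lags = DT * np.arange(1, 10)
        for K, alpha in ((0.03, 0.45), (0.02, 1.0)):
            curve = MSDCurve(lags, K * lags ** alpha)
            fit = fit_anomalous(curve, 5, 0.0)
            assert fit.alpha == pytest.approx(alpha, abs=1e-12)
            assert fit.K_alpha == pytest.approx(K, rel=1e-12)

    def test_offset_corrected_fit_exact(self):
        lags = DT * np.arange(1, 10)
        curve = MSDCurve(lags, 0.03 * lags ** 0.5 + 0.0036)
        fit = fit_anomalous(curve, 5, 0.0036)
        assert fit.alpha == pytest.approx(0.5, abs=1e-12)
        assert fit.K_alpha == pytest.approx(0.03, rel=1e-9)

    def test_overcorrection_rejected(self):
        lags = DT * np.arange(1, 10)
        curve = MSDCurve(lags, 0.001 * lags ** 0.5)
        with pytest.raises(FitDomainError):
            fit_anomalous(curve, 5, 1.0)


def _static_series(mask, n_frames=40, pixel_size=1.0):
    return MaskSeries.static(mask, n_frames, pixel_size)


class TestAssignment:
    def _track_through(self, xs, ys):
        n = len(xs)
        return TrajectorySet(
            [Trajectory(0, np.arange(n), np.array(xs, float),
                        np.array(ys, float))],
            frame_interval=DT, pixel_size=1.0)

    def test_long_inside_run_kept(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        tracks = self._track_through([6.5] * 12, [6.5] * 12)
        segs = assign_tracks_to_masks(tracks, _static_series(mask), 10)
        assert len(segs) == 1
        assert segs[0].label == "inside" and len(segs[0]) == 12

    def test_short_run_discarded(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        tracks = self._track_through([6.5] * 9, [6.5] * 9)
        assert assign_tracks_to_masks(tracks, _static_series(mask), 10) == []

    def test_alternating_labels_no_segments(self):
        mask = np.zeros((20, 20), bool)
        mask[5:10, 5:10] = True
        xs = ([6.5] * 5 + [15.5] * 5) * 3
        tracks = self._track_through(xs, [6.5] * 30)
        assert assign_tracks_to_masks(tracks, _static_series(mask), 10) == []

    def test_split_at_border_crossing(self):
        mask = np.zeros((20, 20), bool)
        mask[:, :10] = True
        xs = [5.5] * 15 + [15.5] * 15
        tracks = self._track_through(xs, [5.5] * 30)
        segs = assign_tracks_to_masks(tracks, _static_series(mask), 10)
        assert [s.label for s in segs] == ["inside", "outside"]
        assert [len(s) for s in segs] == [15, 15]

    def test_frames_outside_epochs_rejected(self):
        mask = np.zeros((20, 20), bool)
        series = MaskSeries([mask], [(0, 5)], 1.0)
        tracks = self._track_through([1.0] * 10, [1.0] * 10)
        with pytest.raises(ParameterError):
            assign_tracks_to_masks(tracks, series, 3)


class TestResampledAlpha:
    def test_analytic_offset_cancellation(self):
        # MSD(n) = n**0.5 + c: v(4, dt)=1, v(4, 2dt)=sqrt(2) -> alpha = 0.5
        for c in (0.0, 0.1, 5.0):
            n = np.arange(1, 10)
            m1 = np.sqrt(n) + c
            m2 = np.sqrt(2 * n) + c
            alpha, lags = _alpha_from_curves(m1, m2)
            assert alpha == pytest.approx(0.5, abs=1e-12)
            assert 4 in lags

    def test_noisy_fbm_recovered_naive_biased(self):
        tracks = generate_fbm_tracks(800, 30, DT, 0.03, 0.5, seed=5)
        noisy = [add_localization_noise(t, 0.03, 100 + i)
                 for i, t in enumerate(tracks)]
        est = resampled_alpha(noisy, min_track_length=20, frame_interval=DT)
        assert est.alpha == pytest.approx(0.5, abs=0.05)
        naive = fit_anomalous(ea_ta_msd(noisy, DT, truncate=10), 5, 0.0)
        assert naive.alpha < est.alpha - 0.05  # static error biases it low

    def test_dataset_sd_is_sample_sd(self):
        datasets = [generate_fbm_tracks(150, 30, DT, 0.03, 0.5, seed=s)
                    for s in (1, 2, 3)]
        est = resampled_alpha_datasets(datasets, 20, DT)
        assert est.per_dataset.size == 3
        assert est.sd_across_datasets == pytest.approx(
            np.std(est.per_dataset, ddof=1))
        assert est.alpha == pytest.approx(est.per_dataset.mean())


class TestCompareRealVsRandom:
    def test_zero_shift_null_gives_zero_deltas(self):
        cfg = SceneConfig(seed=13, n_tracks=400)
        scene = generate_scene(cfg, render_images=False)
        series = _static_series(scene.combined_region_mask,
                                cfg.n_frames, cfg.pixel_size)
        comp = compare_real_vs_random(
            scene.trajectories, series, scene.nucleus_mask, n_random=2,
            seed=0, max_shift=0)
        assert comp.delta_K == pytest.approx(0.0, abs=1e-12)
        assert comp.delta_alpha == pytest.approx(0.0, abs=1e-12)

    def test_labels_partition_segments(self, spt_scene):
        series = _static_series(spt_scene.combined_region_mask,
                                spt_scene.config.n_frames,
                                spt_scene.config.pixel_size)
        segs = assign_tracks_to_masks(spt_scene.trajectories, series, 10)
        inside = segments_with_label(segs, "inside")
        outside = segments_with_label(segs, "outside")
        assert len(inside) + len(outside) == len(segs)
        assert inside and outside
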