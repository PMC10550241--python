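"""Region tracking, trace extraction, event calling and cross-correlation."""

import numpy as np
import pytest

from ptmtrack.errors import DegenerateInputError, EmptyEnsembleError
from ptmtrack.masks import MaskSeries
from ptmtrack.regions import (RegionTrack, RegionTrackSkeleton,
                              align_at_events, call_events,
                              extract_region_trace, interpolate_gaps,
                              link_regions, rescale_intensity,
                              temporal_cross_correlation)
from ptmtrack.synthetic import generate_region_traces


def _region_track(traces, cadence=1.0):
    n = len(next(iter(traces.values())))
    return RegionTrack(0, np.arange(n) * cadence, np.zeros((n, 2)),
                       np.zeros(n), {k: np.asarray(v, float)
                                     for k, v in traces.items()},
                       np.zeros(n, bool))


class TestRescale:
    def test_mean_maps_to_zero_fig1(self):
        vals = np.arange(101.0)
        out = rescale_intensity(vals, "fig1")
        assert out[50] == pytest.approx(0.0)

    def test_quantile_anchors(self):
        vals = np.arange(101.0)
        out = rescale_intensity(vals, "quantile_anchor")
        assert np.interp(2.5, vals, out) == pytest.approx(-1.0)
        assert np.interp(97.5, vals, out) == pytest.approx(1.0)

    def test_fig1_worked_value(self):
        vals = np.arange(101.0)
        out = rescale_intensity(vals, "fig1")
        assert out[-1] == pytest.approx((100 - 50) / 95.0)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateInputError):
            rescale_intensity(np.full(10, 3.0))

    def test_order_preserved(self, rng):
        vals = rng.normal(size=500)
        for variant in ("fig1", "quantile_anchor"):
            out = rescale_intensity(vals, variant)
            assert np.array_equal(np.argsort(out), np.argsort(vals))


def _series_from_positions(positions, shape=(40, 40), size=2):
    """One square component per frame at the given (row, col) positions;
    None means the component is absent that frame."""
    masks = []
    for pos in positions:
        m = np.zeros(shape, bool)
        if pos is not None:
            r, c = pos
            m[r:r + size, c:c + size] = True
        masks.append(m)
    return MaskSeries(masks, [(i, i + 1) for i in range(len(masks))], 0.096)


class TestLinking:
    def test_stationary_component_single_track(self):
        series = _series_from_positions([(10, 10)] * 6)
        tracks = link_regions(series)
        assert len(tracks) == 1 and len(tracks[0].frames) == 6

    def test_distant_components_not_linked(self):
        series = _series_from_positions([(5, 5), (30, 30)])
        tracks = link_regions(series, max_link=10)
        assert len(tracks) == 2

    def test_gap_closed_within_limits(self):
        series = _series_from_positions(
            [(10, 10), (10, 10), None, None, (11, 11), (11, 11)])
        tracks = link_regions(series, max_gap_frames=2, max_gap_dist=3)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 1, 4, 5]

    def test_long_gap_starts_new_track(self):
        series = _series_from_positions(
            [(10, 10), None, None, None, (10, 10)])
        tracks = link_regions(series, max_gap_frames=2)
        assert len(tracks) == 2


class TestTraceExtraction:
    def test_member_pixels_follow_chebyshev_rule(self):
        # a 13x13 block: member set = block & 5-px Chebyshev box -> 11x11
        shape = (40, 40)
        m = np.zeros(shape, bool)
        m[10:23, 10:23] = True
        series = MaskSeries([m], [(0, 1)], 0.096)
        rng = np.random.default_rng(0)
        stack = {"h2b": rng.uniform(0, 1, (1, *shape))}
        nucleus = np.ones(shape, bool)
        sk = RegionTrackSkeleton(0, [0], [np.array([16.0, 16.0])])
        track = extract_region_trace(sk, series, stack, nucleus,
                                     time_interval_min=2.0)
        assert track.areas[0] == 121

    def test_gap_interpolation_flagged(self):
        filled, gap = interpolate_gaps(np.array([0.2, np.nan, 0.4]))
        assert filled[1] == pytest.approx(0.3)
        assert gap.tolist() == [False, True, False]

    def test_interpolated_fraction_matches_dropout(self, rng):
        # ~3% missing points -> ~3% flagged
        n, n_tracks = 100, 60
        flagged = total = 0
        for i in range(n_tracks):
            vals = rng.normal(size=n)
            drop = rng.random(n) < 0.03
            drop[[0, -1]] = False
            vals[drop] = np.nan
            filled, gap = interpolate_gaps(vals)
            flagged += gap.sum()
            total += n
        assert flagged / total == pytest.approx(0.03, abs=0.01)


class TestEvents:
    @staticmethod
    def _bump_track(length=60, center=30, amplitude=0.3, width=3.0):
        t = np.arange(length)
        return amplitude * np.exp(-0.5 * ((t - center) / width) ** 2)

    def test_single_bump_called_once(self):
        events = call_events(self._bump_track(amplitude=0.3))
        assert events.tolist() == [30]

    def test_subthreshold_prominence_ignored(self):
        events = call_events(self._bump_track(amplitude=0.10))
        assert events.size == 0

    def test_short_tracks_ignored(self):
        events = call_events(self._bump_track(length=25, center=12))
        assert events.size == 0

    def test_edge_events_removed(self):
        events = call_events(self._bump_track(center=5))
        assert events.size == 0

    def test_trough_polarity(self):
        events = call_events(-self._bump_track(), polarity="trough")
        assert events.tolist() == [30]


class TestAlignment:
    def test_identical_windows_zero_sem(self):
        trace = TestEvents._bump_track()
        tracks = [_region_track({"a": trace}), _region_track({"a": trace})]
        out = align_at_events(tracks, [np.array([30]), np.array([30])],
                              window=5)
        assert out.n_events == 2
        assert np.allclose(out.ci95["a"], 0.0)
        assert np.allclose(out.mean["a"], trace[25:36])

    def test_single_event_ci_undefined(self):
        tracks = [_region_track({"a": TestEvents._bump_track()})]
        out = align_at_events(tracks, [np.array([30])], window=5)
        assert np.all(np.isnan(out.ci95["a"]))

    def test_no_events_raises(self):
        tracks = [_region_track({"a": np.zeros(40)})]
        with pytest.raises(EmptyEnsembleError):
            align_at_events(tracks, [np.empty(0, int)], window=5)

    def test_bump_amplitude_recovered(self, rng):
        # +0.2 bump injected in channel b at every event
        n_tracks, length, w = 200, 61, 10
        bump = 0.2 * np.exp(-0.5 * ((np.arange(-w, w + 1)) / 2.0) ** 2)
        tracks, events = [], []
        for i in range(n_tracks):
            b = rng.normal(0, 0.1, length)
            b[30 - w:31 + w] += bump
            tracks.append(_region_track({"b": b}))
            events.append(np.array([30]))
        out = align_at_events(tracks, events, window=w)
        assert out.mean["b"][w] == pytest.approx(0.2, abs=0.02)


class TestCrossCorrelation:
    def test_identical_channels_unit_correlation(self, rng):
        tracks = [_region_track({"a": (v := rng.normal(size=50)), "b": v})
                  for _ in range(5)]
        xc = temporal_cross_correlation(tracks, ("a", "b"), max_lag=3,
                                        n_boot=10, seed=0)
        assert xc.weighted_r[3] == pytest.approx(1.0)

    def test_sign_flip(self, rng):
        tracks = [_region_track({"a": (v := rng.normal(size=50)), "b": -v})
                  for _ in range(5)]
        xc = temporal_cross_correlation(tracks, ("a", "b"), max_lag=2,
                                        n_boot=10, seed=0)
        assert xc.weighted_r[2] == pytest.approx(-1.0)

    def test_length_weighted_mean_hand_case(self, rng):
        # r = {1, 0} with overlaps {30, 10} -> weighted mean 0.75 at lag 0
        v = rng.normal(size=30)
        t1 = _region_track({"a": v, "b": v})
        a2 = np.tile([1.0, -1.0], 5)
        b2 = np.tile([1.0, 1.0, -1.0, -1.0], 3)[:10] - 0.2
        assert abs(np.corrcoef(a2, b2)[0, 1]) < 1e-12
        t2 = _region_track({"a": a2, "b": b2})
        xc = temporal_cross_correlation([t1, t2], ("a", "b"), max_lag=0,
                                        n_boot=10, seed=0)
        assert xc.weighted_r[0] == pytest.approx(0.75)

    def test_lag_convention_b_delayed(self):
        # b lags a by 2 steps -> peak at positive lag +2 (cadence 1)
        t = np.arange(80, dtype=float)
        sig = np.sin(2 * np.pi * t / 16)
        tracks = [_region_track({"a": sig, "b": np.roll(sig, 2)})]
        xc = temporal_cross_correlation(tracks, ("a", "b"), max_lag=4,
                                        n_boot=5, seed=0)
        assert xc.lags[np.argmax(xc.weighted_r)] == pytest.approx(2.0)

    def test_coupling_sign_recovered(self):
        for rho in (0.5, -0.5):
            tracks = generate_region_traces(300, 100, rho, 0.05, seed=11)
            xc = temporal_cross_correlation(tracks, ("h3k27ac", "ser5ph"),
                                            max_lag=2, n_boot=50, seed=1)
            r0 = xc.weighted_r[2]
            assert np.sign(r0) == np.sign(rho)
            assert r0 == pytest.approx(rho, abs=0.1)
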