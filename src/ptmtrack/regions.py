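"""Minutes-to-hours dynamics of tracked PTM-enriched territories.

Covers intensity rescaling of nuclear images, greedy centroid linking of
segmented regions through time, extraction of per-region three-channel
intensity traces (with linear interpolation over track gaps), peak/trough
calling, event-triggered averaging, and length-weighted bootstrap
cross-correlation between channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .errors import (DegenerateInputError, EmptyEnsembleError, ParameterError)
from .masks import MaskSeries, _STRUCT8

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# intensity rescaling
# ---------------------------------------------------------------------------

def rescale_intensity(values: np.ndarray,
                      variant: str = "quantile_anchor") -> np.ndarray:
    """Rescale nuclear intensities by their 2.5/97.5 percentile span.

    ``variant="fig1"`` centers on the mean: (I - <I>) / (I_97.5 - I_2.5).
    ``variant="quantile_anchor"`` maps the 2.5 percentile to -1 and the
    97.5 percentile to +1.  Both are order-preserving affine maps; they
    differ by a shift unless the sample is symmetric about its mean.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2 or np.min(values) == np.max(values):
        raise DegenerateInputError("need >= 2 distinct values to rescale")
    q_lo, q_hi = np.percentile(values, [2.5, 97.5])
    span = q_hi - q_lo
    if span == 0:
        raise DegenerateInputError("2.5 and 97.5 percentiles coincide")
    if variant == "fig1":
        return (values - values.mean()) / span
    if variant == "quantile_anchor":
        return 2.0 * (values - q_lo) / span - 1.0
    raise ParameterError(f"unknown rescaling variant {variant!r}")


def rescale_image(image: np.ndarray, nucleus: np.ndarray,
                  variant: str = "quantile_anchor") -> np.ndarray:
    """Apply :func:`rescale_intensity` over nuclear pixels of one frame.

    Pixels outside the nucleus are set to NaN so they can never leak into
    region averages.
    """
    nucleus = np.asarray(nucleus, dtype=bool)
    out = np.full(image.shape, np.nan)
    out[nucleus] = rescale_intensity(np.asarray(image, float)[nucleus],
                                     variant)
    return out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RegionTrack:
    """One tracked enriched region: centroids plus channel intensity traces."""

    track_id: int
    times: np.ndarray                  # minutes, fixed cadence
    centroids: np.ndarray              # (T, 2) (row, col) pixels; NaN on gaps
    areas: np.ndarray                  # member-pixel count per time
    traces: Dict[str, np.ndarray]      # channel -> mean rescaled intensity
    interpolated: np.ndarray           # bool per time point

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.traces.values()}
        lengths.add(len(self.times))
        if len(lengths) != 1:
            raise ParameterError("trace lengths must match times")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def interpolated_fraction(self) -> float:
        return float(np.mean(self.interpolated)) if len(self) else 0.0


@dataclass
class RegionTrackSkeleton:
    """Linked centroids before intensity extraction."""

    track_id: int
    frames: List[int]
    centroids: List[np.ndarray]        # (row, col) pixels


@dataclass
class EventAlignment:
    offsets: np.ndarray                # time steps relative to the event
    mean: Dict[str, np.ndarray]
    ci95: Dict[str, np.ndarray]        # NaN where n = 1
    n_events: int


@dataclass
class CrossCorrelation:
    lags: np.ndarray                   # minutes (or steps * cadence)
    weighted_r: np.ndarray
    bootstrap_sd: np.ndarray
    n_tracks: int
    n_boot: int
    n_excluded: int = 0                # zero-variance track/lag exclusions


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def _frame_centroids(mask: np.ndarray) -> List[np.ndarray]:
    labeled, n = ndimage.label(np.asarray(mask, bool), structure=_STRUCT8)
    if n == 0:
        return []
    return [np.asarray(c) for c in
            ndimage.center_of_mass(mask, labeled, range(1, n + 1))]


def link_regions(mask_series: MaskSeries, max_link: float = 10.0,
                 max_gap_frames: int = 2, max_gap_dist: float = 3.0
                 ) -> List[RegionTrackSkeleton]:
    """Greedy frame-to-frame nearest-neighbor linking of region centroids.

    Adjacent-frame links must be within ``max_link`` pixels; a track missing
    for up to ``max_gap_frames`` frames may be reclaimed within
    ``max_gap_dist`` pixels.  Matching is one-to-one per frame pair, closest
    pairs first; unmatched detections seed new tracks.
    """
    tracks: List[RegionTrackSkeleton] = []
    open_tracks: List[RegionTrackSkeleton] = []
    next_id = 0
    start, stop = mask_series.frame_range
    for frame in range(start, stop):
        detections = _frame_centroids(mask_series.mask_for_frame(frame))
        candidates = []
        for ti, tr in enumerate(open_tracks):
            gap = frame - tr.frames[-1] - 1
            limit = max_link if gap == 0 else (
                max_gap_dist if gap <= max_gap_frames else None)
            if limit is None:
                continue
            for di, det in enumerate(detections):
                dist = float(np.hypot(*(det - tr.centroids[-1])))
                if dist <= limit:
                    candidates.append((dist, ti, di))
        used_t: set = set()
        used_d: set = set()
        for dist, ti, di in sorted(candidates):
            if ti in used_t or di in used_d:
                continue
            used_t.add(ti)
            used_d.add(di)
            open_tracks[ti].frames.append(frame)
            open_tracks[ti].centroids.append(detections[di])
        for di, det in enumerate(detections):
            if di not in used_d:
                tr = RegionTrackSkeleton(next_id, [frame], [det])
                next_id += 1
                open_tracks.append(tr)
                tracks.append(tr)
        open_tracks = [tr for tr in open_tracks
                       if frame - tr.frames[-1] - 1 <= max_gap_frames]
    return tracks


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------

def _member_pixels(mask: np.ndarray, centroid: np.ndarray,
                   reach: int = 5) -> np.ndarray:
    """Connected foreground pixels within ``reach`` pixels (Chebyshev) of
    the centroid; empty array when no foreground is nearby."""
    labeled, n = ndimage.label(np.asarray(mask, bool), structure=_STRUCT8)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    r0 = int(round(centroid[0]))
    c0 = int(round(centroid[1]))
    rows, cols = mask.shape
    r0 = min(max(r0, 0), rows - 1)
    c0 = min(max(c0, 0), cols - 1)
    label = labeled[r0, c0]
    if label == 0:
        # concave region: pick the nearest foreground pixel within reach
        rlo, rhi = max(r0 - reach, 0), min(r0 + reach + 1, rows)
        clo, chi = max(c0 - reach, 0), min(c0 + reach + 1, cols)
        local = np.argwhere(labeled[rlo:rhi, clo:chi] > 0)
        if local.size == 0:
            return np.empty((0, 2), dtype=int)
        local = local + [rlo, clo]
        best = local[np.argmin(np.abs(local - [r0, c0]).max(axis=1))]
        label = labeled[best[0], best[1]]
    coords = np.argwhere(labeled == label)
    cheb = np.abs(coords - [r0, c0]).max(axis=1) <= reach
    return coords[cheb]


def interpolate_gaps(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Fill NaNs by linear interpolation; returns (filled, was_gap)."""
    values = np.asarray(values, dtype=float)
    gap = ~np.isfinite(values)
    if gap.all():
        raise DegenerateInputError("trace contains no measured points")
    if gap.any():
        idx = np.arange(values.size)
        values = values.copy()
        values[gap] = np.interp(idx[gap], idx[~gap], values[~gap])
    return values, gap


def extract_region_trace(skeleton: RegionTrackSkeleton,
                         mask_series: MaskSeries,
                         channel_stacks: Dict[str, np.ndarray],
                         nucleus: np.ndarray,
                         time_interval_min: float = 3.0,
                         reach: int = 5,
                         variant: str = "quantile_anchor") -> RegionTrack:
    """Mean rescaled channel intensities of one linked region through time.

    Each frame of every channel is rescaled over the nucleus before
    averaging.  The member-pixel set at a time point is the mask component
    at the linked centroid intersected with its ``reach``-pixel Chebyshev
    neighborhood; frames missing from the skeleton (or with an empty member
    set) become gaps, filled by linear interpolation and flagged.
    """
    first, last = skeleton.frames[0], skeleton.frames[-1]
    span = range(first, last + 1)
    n = len(span)
    channels = list(channel_stacks)
    raw = {ch: np.full(n, np.nan) for ch in channels}
    centroids = np.full((n, 2), np.nan)
    areas = np.zeros(n)
    by_frame = dict(zip(skeleton.frames, skeleton.centroids))
    rescaled_cache: Dict[Tuple[str, int], np.ndarray] = {}
    for i, frame in enumerate(span):
        if frame not in by_frame:
            continue
        centroid = by_frame[frame]
        mask = mask_series.mask_for_frame(frame)
        members = _member_pixels(mask, centroid, reach)
        if members.size == 0:
            continue
        centroids[i] = centroid
        areas[i] = len(members)
        for ch in channels:
            key = (ch, frame)
            if key not in rescaled_cache:
                rescaled_cache[key] = rescale_image(
                    channel_stacks[ch][frame], nucleus, variant)
            vals = rescaled_cache[key][members[:, 0], members[:, 1]]
            raw[ch][i] = float(np.nanmean(vals))
    traces = {}
    flags = np.zeros(n, dtype=bool)
    for ch in channels:
        filled, gap = interpolate_gaps(raw[ch])
        traces[ch] = filled
        flags |= gap
    times = (np.asarray(list(span)) - first) * time_interval_min
    return RegionTrack(skeleton.track_id, times, centroids, areas, traces,
                       flags)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def call_events(trace: np.ndarray, prominence: float = 0.15,
                min_width: float = 2, min_separation: int = 10,
                min_track_len: int = 30, edge_margin: int = 10,
                polarity: str = "peak") -> np.ndarray:
    """Indices of peaks (or troughs) in an intensity trace.

    Tracks shorter than ``min_track_len`` yield no events; events within
    ``edge_margin`` points of either end are discarded.
    """
    trace = np.asarray(trace, dtype=float)
    if polarity not in ("peak", "trough"):
        raise ParameterError("polarity must be 'peak' or 'trough'")
    if trace.size < min_track_len:
        return np.empty(0, dtype=int)
    signal = -trace if polarity == "trough" else trace
    idx, _ = find_peaks(signal, prominence=prominence, width=min_width,
                        distance=min_separation)
    keep = (idx >= edge_margin) & (idx < trace.size - edge_margin)
    return idx[keep]


def align_at_events(tracks: Sequence[RegionTrack],
                    events: Sequence[np.ndarray],
                    window: int = 10,
                    channels: Optional[Sequence[str]] = None
                    ) -> EventAlignment:
    """Event-triggered average of every channel over +/- ``window`` steps.

    Only events at least ``window`` steps from both track ends contribute.
    The 95% CI is 1.96 * SEM across events (NaN when a single event).
    """
    if channels is None:
        channels = list(tracks[0].traces) if tracks else []
    windows: Dict[str, List[np.ndarray]] = {ch: [] for ch in channels}
    for track, ev in zip(tracks, events):
        for e in np.atleast_1d(np.asarray(ev, dtype=int)):
            if e - window < 0 or e + window >= len(track):
                continue
            for ch in channels:
                windows[ch].append(track.traces[ch][e - window:e + window + 1])
    n_events = len(next(iter(windows.values()))) if channels else 0
    if n_events == 0:
        raise EmptyEnsembleError("no events fall fully inside their tracks")
    offsets = np.arange(-window, window + 1)
    mean: Dict[str, np.ndarray] = {}
    ci95: Dict[str, np.ndarray] = {}
    for ch in channels:
        arr = np.stack(windows[ch])
        mean[ch] = arr.mean(axis=0)
        if arr.shape[0] > 1:
            sem = arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            ci95[ch] = 1.96 * sem
        else:
            ci95[ch] = np.full(arr.shape[1], np.nan)
    return EventAlignment(offsets, mean, ci95, n_events)


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def _lagged_pearson(a: np.ndarray, b: np.ndarray,
                    lag: int) -> Tuple[Optional[float], int]:
    """Pearson r between a[t] and b[t + lag] over their overlap.

    Positive lag means channel B is delayed relative to A.  Returns
    (None, n) when the overlap is too short or has zero variance.
    """
    if lag >= 0:
        x, y = a[:len(a) - lag or None], b[lag:]
    else:
        x, y = a[-lag:], b[:len(b) + lag or None]
    n = min(len(x), len(y))
    x, y = x[:n], y[:n]
    if n < 3:
        return None, n
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None, n
    r = float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))
    return r, n


def _correlation_tables(tracks: Sequence[RegionTrack], channel_pair, lags
                        ) -> Tuple[np.ndarray, np.ndarray, int]:
    """Per-track, per-lag Pearson r and pair-count weight matrices.

    Weight = number of overlapping points at that lag; excluded track/lag
    pairs (short overlap or zero variance) get weight 0.
    """
    ch_a, ch_b = channel_pair
    r_mat = np.zeros((len(tracks), len(lags)))
    w_mat = np.zeros((len(tracks), len(lags)))
    n_excluded = 0
    for ti, tr in enumerate(tracks):
        for li, lag in enumerate(lags):
            r, n = _lagged_pearson(tr.traces[ch_a], tr.traces[ch_b], lag)
            if r is None:
                n_excluded += 1
                continue
            r_mat[ti, li] = r
            w_mat[ti, li] = n
    return r_mat, w_mat, n_excluded


def _weighted_curve(r_mat: np.ndarray, w_mat: np.ndarray) -> np.ndarray:
    den = w_mat.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, (r_mat * w_mat).sum(axis=0) / den, np.nan)


def temporal_cross_correlation(tracks: Sequence[RegionTrack],
                               channel_pair: Tuple[str, str] = ("h3k27ac",
                                                                "ser5ph"),
                               max_lag: int = 10, n_boot: int = 1000,
                               seed=None) -> CrossCorrelation:
    """Length-weighted mean lagged Pearson correlation with bootstrap SD.

    Per lag, each track contributes its Pearson r over the overlapping
    samples, weighted by the number of overlapping points; the error is the
    SD of the weighted curve over ``n_boot`` resamplings of tracks with
    replacement (resample size = number of tracks).
    """
    if not tracks:
        raise EmptyEnsembleError("no tracks for cross-correlation")
    cadence = (tracks[0].times[1] - tracks[0].times[0]
               if len(tracks[0]) > 1 else 1.0)
    lags = np.arange(-max_lag, max_lag + 1)
    tracks = list(tracks)
    r_mat, w_mat, n_excluded = _correlation_tables(tracks, channel_pair, lags)
    curve = _weighted_curve(r_mat, w_mat)
    if n_excluded:
        logger.info("cross-correlation: %d zero-variance/short track-lag "
                    "pairs excluded", n_excluded)
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, len(lags)))
    for b in range(n_boot):
        idx = rng.integers(0, len(tracks), size=len(tracks))
        boot[b] = _weighted_curve(r_mat[idx], w_mat[idx])
    return CrossCorrelation(lags * cadence, curve,
                            np.nanstd(boot, axis=0, ddof=1),
                            n_tracks=len(tracks), n_boot=n_boot,
                            n_excluded=n_excluded)
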