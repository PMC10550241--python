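"""Mask-conditioned single-nucleosome diffusion statistics.

The anomalous-diffusion law fitted here is

    EA-TA-MSD(t_lag) ~= K_alpha * t_lag**alpha,

with the time-averaged MSD of one track of N points

    msd(n*dt) = 1/(N-n) * sum_j |r[(j+n)dt] - r[j*dt]|^2 .

Tracks are assigned to binary enrichment masks by their sub-pixel
coordinates, split where the inside/outside label changes, and only runs of
at least ``min_consecutive`` frames are kept.  Per-cell contrasts are
measured against morphology-preserving randomized masks: segments pooled
across the randomizations are fitted once and subtracted from the real-mask
fit, cancelling the selection bias that any mask imposes on the tracks it
captures.

Static localization error adds ~4*sigma^2 to every 2-D MSD value; the
module offers a two-point intercept extrapolation and a weighted
power-law-plus-offset fit to estimate it, and a subsampling ("every other
frame") estimator of alpha that cancels both static and dynamic errors
exactly for power-law MSDs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .errors import (EmptyEnsembleError, FitDomainError,
                     InsufficientSegmentsError, ParameterError)
from .masks import MaskSeries, randomize_mask
from .tracks import Trajectory, TrajectorySet

logger = logging.getLogger(__name__)

INSIDE, OUTSIDE = "inside", "outside"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    lags: np.ndarray                 # seconds, increasing
    values: np.ndarray               # um^2
    sem: Optional[np.ndarray] = None  # across tracks; None for single-track
    n_tracks: int = 1
    correction_offset: float = 0.0   # um^2 already subtracted from values

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0):
            raise ParameterError("lags must be positive and increasing")


@dataclass
class DiffusionFit:
    K_alpha: float                   # um^2 / s^alpha
    alpha: float
    fit_lags: int
    r_squared: float
    offset: float = 0.0              # um^2 subtracted before the fit
    n_tracks: int = 0


@dataclass
class CellComparison:
    cell_id: object
    fit_real: DiffusionFit
    fit_random: DiffusionFit         # pooled over all randomizations
    delta_K: float
    delta_alpha: float
    pct_delta_K: float
    pct_delta_alpha: float
    n_randomizations: int


@dataclass
class ResampledAlphaEstimate:
    alpha: float
    sd_across_datasets: Optional[float]
    min_track_length: int
    lags_used: np.ndarray            # frame lags entering the average
    per_dataset: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# mask assignment
# ---------------------------------------------------------------------------

def _pixel_indices(track: Trajectory, pixel_size: float) -> np.ndarray:
    """Containing pixel of each sub-pixel position: floor(pos/px), row = y."""
    rows = np.floor(track.y / pixel_size).astype(int)
    cols = np.floor(track.x / pixel_size).astype(int)
    return np.column_stack([rows, cols])


def assign_tracks_to_masks(tracks: TrajectorySet, mask_series: MaskSeries,
                           min_consecutive: int = 10) -> List[Trajectory]:
    """Split tracks at inside/outside label changes; keep long runs.

    Every position is classified by whether its containing pixel of the
    governing epoch mask is foreground.  Maximal constant-label runs of
    consecutive frames with at least ``min_consecutive`` points are emitted
    as labeled segment trajectories.
    """
    start, stop = mask_series.frame_range
    segments: List[Trajectory] = []
    for track in tracks:
        if track.frames[0] < start or track.frames[-1] >= stop:
            raise ParameterError(
                f"track {track.track_id} extends outside mask epochs")
        pix = _pixel_indices(track, mask_series.pixel_size)
        shape = mask_series.masks[0].shape
        labels = np.empty(len(track), dtype=bool)
        for i, frame in enumerate(track.frames):
            mask = mask_series.mask_for_frame(int(frame))
            r, c = pix[i]
            labels[i] = (0 <= r < shape[0] and 0 <= c < shape[1]
                         and bool(mask[r, c]))
        # run boundaries: label changes or non-consecutive frames
        breaks = np.flatnonzero((labels[1:] != labels[:-1])
                                | (np.diff(track.frames) != 1))
        bounds = np.concatenate([[0], breaks + 1, [len(track)]])
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < min_consecutive:
                continue
            segments.append(Trajectory(
                track.track_id, track.frames[b0:b1], track.x[b0:b1],
                track.y[b0:b1], label=INSIDE if labels[b0] else OUTSIDE))
    return segments


def segments_with_label(segments: Sequence[Trajectory],
                        label: str) -> List[Trajectory]:
    return [s for s in segments if s.label == label]


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def ta_msd(track: Trajectory, max_lag: Optional[int] = None,
           frame_interval: float = 1.0) -> MSDCurve:
    """Time-averaged MSD of one track for frame lags n = 1..max_lag."""
    if len(track) < 2:
        raise ParameterError("track needs >= 2 points for a TA-MSD")
    if not track.is_consecutive():
        raise ParameterError("TA-MSD requires consecutive frames")
    n_pts = len(track)
    if max_lag is None:
        max_lag = n_pts - 1
    if max_lag >= n_pts:
        logger.warning("max_lag %d >= track length %d; trimming", max_lag,
                       n_pts)
        max_lag = n_pts - 1
    pos = track.positions
    values = np.empty(max_lag)
    for n in range(1, max_lag + 1):
        d = pos[n:] - pos[:-n]
        values[n - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    lags = np.arange(1, max_lag + 1) * frame_interval
    return MSDCurve(lags, values, n_tracks=1)


def ea_ta_msd(segments: Sequence[Trajectory], frame_interval: float,
              truncate: Optional[int] = 10,
              max_lag: Optional[int] = None) -> MSDCurve:
    """Unweighted mean of single-track TA-MSDs, SEM across tracks.

    Tracks are first truncated to their first ``truncate`` frames so every
    track contributes the same time span (suppresses aging/selection bias
    from tracks leaving the focal plane).  Tracks shorter than 2 points
    after truncation are dropped.
    """
    if truncate is not None:
        segments = [s.truncate(truncate) for s in segments]
    segments = [s for s in segments if len(s) >= 2]
    if not segments:
        raise EmptyEnsembleError("no usable segments for EA-TA-MSD")
    min_len = min(len(s) for s in segments)
    lag_cap = min_len - 1 if max_lag is None else min(max_lag, min_len - 1)
    curves = np.stack([
        ta_msd(s, lag_cap, frame_interval).values for s in segments])
    sem = (curves.std(axis=0, ddof=1) / np.sqrt(len(segments))
           if len(segments) > 1 else np.zeros(lag_cap))
    lags = np.arange(1, lag_cap + 1) * frame_interval
    return MSDCurve(lags, curves.mean(axis=0), sem=sem,
                    n_tracks=len(segments))


# ---------------------------------------------------------------------------
# localization-error offset and power-law fit
# ---------------------------------------------------------------------------

def estimate_localization_offset(curve: MSDCurve,
                                 method: str = "two_point") -> float:
    """Static-error MSD offset (um^2); divide by 4 and root for sigma.

    ``two_point``: linear extrapolation of the first two lag points to lag
    zero, floored at 0.  Unbiased for linear MSDs; for a subdiffusive power
    law it over-estimates by K*dt^alpha*(2 - 2**alpha).
    ``power_law``: SEM-weighted least-squares fit of K*t**alpha + c over all
    available lags, returning c.  Preferred when the curve is subdiffusive.
    """
    if curve.values.size < 2:
        raise ParameterError("need >= 2 lags to estimate the offset")
    if method == "two_point":
        v1, v2 = curve.values[:2]
        return float(max(2.0 * v1 - v2, 0.0))
    if method == "power_law":
        t, y = curve.lags, curve.values
        sigma = None
        if curve.sem is not None and np.all(np.asarray(curve.sem) > 0):
            sigma = np.asarray(curve.sem)

        def model(t, K, alpha, c):
            return K * t ** alpha + c

        slope0 = max(2.0 * (y[-1] - y[0]) / (t[-1] - t[0]), 1e-12)
        try:
            popt, _ = curve_fit(
                model, t, y, p0=[slope0, 0.5, max(y[0] / 2.0, 1e-9)],
                sigma=sigma, bounds=([0.0, 0.01, 0.0],
                                     [np.inf, 2.0, np.inf]),
                maxfev=10000)
        except RuntimeError:
            return estimate_localization_offset(curve, "two_point")
        return float(popt[2])
    raise ParameterError(f"unknown offset method {method!r}")


def estimate_offset_resampling(segments: Sequence[Trajectory],
                               frame_interval: float,
                               lag_cap: int = 10) -> Tuple[float, float]:
    """Static-error offset via the subsampling alpha estimator.

    Two-stage: (i) alpha from the even/odd-resampling functional ratio
    (offset-free by construction; lags above ``lag_cap`` frames are dropped
    because their time-averaged statistics are noisier), then (ii) an
    SEM-weighted linear fit of K * t**alpha + c to the full-length
    EA-TA-MSD, which is linear in (K, c) once alpha is fixed.  Returns
    (offset, alpha_resampled).  More stable than the free 3-parameter
    power-law fit, whose curvature/offset degeneracy is severe on
    short-lag subdiffusive curves.
    """
    m1 = ea_ta_msd(segments, frame_interval, truncate=None)
    resampled: List[Trajectory] = []
    for s in segments:
        even, odd = _subsample_even_odd(s)
        for r in (even, odd):
            if len(r) >= 2:
                resampled.append(r)
    m2 = ea_ta_msd(resampled, 2.0 * frame_interval, truncate=None)
    n_max = min(m1.values.size, m2.values.size)
    v1 = m1.values[:n_max] - m1.values[0]
    v2 = m2.values[:n_max] - m2.values[0]
    lags = np.arange(1, n_max + 1)
    usable = (v1 > 0) & (v2 > 0) & (lags <= lag_cap)
    if not np.any(usable):
        raise FitDomainError("no usable lag for the resampling offset")
    alpha_rs = float(np.mean(np.log2(v2[usable] / v1[usable])))
    w = 1.0 / np.maximum(np.asarray(m1.sem, float), 1e-12) \
        if m1.sem is not None else np.ones(m1.values.size)
    design = np.column_stack([m1.lags ** alpha_rs, np.ones(m1.lags.size)])
    coef, *_ = np.linalg.lstsq(design * w[:, None], m1.values * w,
                               rcond=None)
    return float(max(coef[1], 0.0)), alpha_rs


def localization_sigma(offset: float) -> float:
    """Per-coordinate localization sd implied by a 2-D MSD offset (4*sigma^2)."""
    return float(np.sqrt(max(offset, 0.0) / 4.0))


def fit_anomalous(curve: MSDCurve, n_points: int = 5,
                  offset: float = 0.0) -> DiffusionFit:
    """OLS fit of log10(MSD - offset) vs log10(t) over the first lags."""
    n_points = min(n_points, curve.values.size)
    y = curve.values[:n_points] - offset
    if np.any(y <= 0):
        raise FitDomainError(
            "offset-corrected MSD non-positive among the fit points")
    logt = np.log10(curve.lags[:n_points])
    logy = np.log10(y)
    slope, intercept = np.polyfit(logt, logy, 1)
    resid = logy - (slope * logt + intercept)
    ss_tot = np.sum((logy - logy.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return DiffusionFit(K_alpha=float(10.0 ** intercept), alpha=float(slope),
                        fit_lags=n_points, r_squared=float(r2),
                        offset=float(offset), n_tracks=curve.n_tracks)


def fit_segments(segments: Sequence[Trajectory], frame_interval: float,
                 truncate: int = 10, fit_points: int = 5,
                 offset_method: Optional[str] = "resampling",
                 offset: Optional[float] = None) -> DiffusionFit:
    """Truncate -> EA-TA-MSD -> offset correction -> 5-point log-log fit.

    The static-error offset may be supplied directly (``offset=``, e.g. one
    shared estimate per cell) or estimated here: ``"resampling"`` uses the
    full-length segments (:func:`estimate_offset_resampling`); the curve
    methods of :func:`estimate_localization_offset` act on the truncated
    ensemble curve; ``None`` skips the correction.
    """
    curve = ea_ta_msd(segments, frame_interval, truncate=truncate)
    if offset is None:
        if offset_method is None:
            offset = 0.0
        elif offset_method == "resampling":
            offset, _ = estimate_offset_resampling(segments, frame_interval)
        else:
            offset = estimate_localization_offset(curve, offset_method)
    return fit_anomalous(curve, n_points=fit_points, offset=offset)


# ---------------------------------------------------------------------------
# real vs randomized masks
# ---------------------------------------------------------------------------

def compare_real_vs_random(tracks: TrajectorySet,
                           real_mask_series: MaskSeries,
                           nucleus: Optional[np.ndarray] = None,
                           n_random: int = 10, seed=None,
                           max_shift: int = 20,
                           min_consecutive: int = 10,
                           min_segments: int = 25,
                           truncate: int = 10, fit_points: int = 5,
                           offset_method: Optional[str] = "resampling"
                           ) -> CellComparison:
    """Per-cell (K, alpha) contrast between a real mask and its null.

    Fits the inside segments of the real mask, then pools the inside
    segments of ``n_random`` independently randomized mask series into one
    ensemble fit, and reports real - randomized differences and percent
    changes relative to the randomized values.

    The static-error offset is a property of the imaging, not of the mask,
    so it is estimated once per cell from all tracks and shared by both
    fits; its estimation error then largely cancels in the differences.
    """
    real_segments = segments_with_label(
        assign_tracks_to_masks(tracks, real_mask_series, min_consecutive),
        INSIDE)
    rng = np.random.default_rng(seed)
    random_segments: List[Trajectory] = []
    for _ in range(n_random):
        rand_masks = [randomize_mask(m, nucleus, max_shift,
                                     rng.integers(0, 2 ** 31)).mask
                      for m in real_mask_series.masks]
        rand_series = MaskSeries(rand_masks, real_mask_series.epoch_frames,
                                 real_mask_series.pixel_size)
        random_segments.extend(segments_with_label(
            assign_tracks_to_masks(tracks, rand_series, min_consecutive),
            INSIDE))
    if len(real_segments) < min_segments \
            or len(random_segments) < min_segments:
        raise InsufficientSegmentsError(
            f"cell {tracks.cell_id}: {len(real_segments)} real / "
            f"{len(random_segments)} randomized segments "
            f"(minimum {min_segments})")
    offset: Optional[float] = None
    if offset_method == "resampling":
        offset, _ = estimate_offset_resampling(list(tracks),
                                               tracks.frame_interval)
    fit_real = fit_segments(real_segments, tracks.frame_interval, truncate,
                            fit_points, offset_method, offset=offset)
    fit_rand = fit_segments(random_segments, tracks.frame_interval, truncate,
                            fit_points, offset_method, offset=offset)
    d_k = fit_real.K_alpha - fit_rand.K_alpha
    d_a = fit_real.alpha - fit_rand.alpha
    return CellComparison(
        cell_id=tracks.cell_id, fit_real=fit_real, fit_random=fit_rand,
        delta_K=d_k, delta_alpha=d_a,
        pct_delta_K=100.0 * d_k / fit_rand.K_alpha,
        pct_delta_alpha=100.0 * d_a / fit_rand.alpha,
        n_randomizations=n_random)


# ---------------------------------------------------------------------------
# resampling estimator of alpha
# ---------------------------------------------------------------------------

def _subsample_even_odd(track: Trajectory) -> Tuple[Trajectory, Trajectory]:
    """Even- and odd-position subsampled copies (frame time doubled)."""
    even = Trajectory(track.track_id, np.arange(len(track.frames[::2])),
                      track.x[::2], track.y[::2], track.label)
    odd = Trajectory(track.track_id, np.arange(len(track.frames[1::2])),
                     track.x[1::2], track.y[1::2], track.label)
    return even, odd


def _alpha_from_curves(msd_orig: np.ndarray, msd_resampled: np.ndarray
                       ) -> Tuple[float, np.ndarray]:
    """alpha from translated MSD functionals indexed by frame lag.

    v1(n) = M1(n) - M1(1), v2(n) = M2(n) - M2(1); because the resampled
    curve lives on a doubled frame time, v2(n) = 2**alpha * v1(n) for a
    power-law MSD, so alpha = mean_n log2[v2(n)/v1(n)] over lags where both
    functionals are positive.  Any constant (static-error) offset cancels
    in the translation.
    """
    n_max = min(len(msd_orig), len(msd_resampled))
    v1 = msd_orig[:n_max] - msd_orig[0]
    v2 = msd_resampled[:n_max] - msd_resampled[0]
    lags = np.arange(1, n_max + 1)
    usable = (v1 > 0) & (v2 > 0)
    if not np.any(usable):
        raise FitDomainError("no lag with both MSD functionals positive")
    alpha = float(np.mean(np.log2(v2[usable] / v1[usable])))
    return alpha, lags[usable]


def resampled_alpha(segments: Sequence[Trajectory],
                    min_track_length: int = 20,
                    frame_interval: float = 1.0) -> ResampledAlphaEstimate:
    """Static/dynamic-error-free alpha from even/odd frame subsampling.

    Original segments (>= ``min_track_length`` points, truncated to that
    length) and their even+odd subsampled copies are ensemble-averaged
    into two TA-MSD curves; alpha comes from the ratio of their translated
    functionals (see :func:`_alpha_from_curves`).
    """
    kept = [s.truncate(min_track_length) for s in segments
            if len(s) >= min_track_length]
    if not kept:
        raise EmptyEnsembleError(
            f"no segments of length >= {min_track_length}")
    resampled: List[Trajectory] = []
    for s in kept:
        even, odd = _subsample_even_odd(s)
        resampled.extend([even, odd])
    m1 = ea_ta_msd(kept, frame_interval, truncate=None)
    m2 = ea_ta_msd(resampled, 2.0 * frame_interval, truncate=None)
    alpha, lags_used = _alpha_from_curves(m1.values, m2.values)
    return ResampledAlphaEstimate(alpha=alpha, sd_across_datasets=None,
                                  min_track_length=min_track_length,
                                  lags_used=lags_used)


def resampled_alpha_datasets(datasets: Sequence[Sequence[Trajectory]],
                             min_track_length: int = 20,
                             frame_interval: float = 1.0
                             ) -> ResampledAlphaEstimate:
    """Average the resampled-alpha estimate over independent datasets.

    The reported spread is the sample SD of the per-dataset alphas.
    """
    per = np.array([
        resampled_alpha(d, min_track_length, frame_interval).alpha
        for d in datasets])
    sd = float(per.std(ddof=1)) if per.size > 1 else None
    return ResampledAlphaEstimate(alpha=float(per.mean()),
                                  sd_across_datasets=sd,
                                  min_track_length=min_track_length,
                                  lags_used=np.empty(0, dtype=int),
                                  per_dataset=per)
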