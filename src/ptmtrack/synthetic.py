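"""Synthetic imaging scenes with known ground truth.

This module fabricates everything the downstream analysis consumes so that
every stage of the pipeline can be validated without raw microscopy data:

* subdiffusive single-nucleosome trajectories as 2-D fractional Brownian
  motion (fBm) with a prescribed anomalous-diffusion law
  ``E[MSD(t)] = K * t**alpha``,
* static localization noise,
* "cells": an elliptical nucleus containing non-overlapping disk-like
  PTM-enriched territories (~1 um^2 cross-section), with trajectories whose
  (K, alpha) differ inside versus outside the territories, rendered
  multi-channel image stacks, and per-territory intensity time traces with a
  controllable inter-channel coupling,
* overdamped Rouse (bead-spring) polymer chains, as an independent physical
  reference whose middle-monomer motion obeys MSD ~ t**0.5 at intermediate
  times.

fBm is synthesized by Davies-Harte circulant embedding of the fractional
Gaussian noise covariance, which is exact in distribution; a Cholesky
factorization is used as a fallback should the embedding fail to be
nonnegative definite.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, ParameterError
from .tracks import Trajectory, TrajectorySet

#: Channel names used throughout the package, in rendering order.
CHANNELS = ("h3k27ac", "ser5ph", "h2b")

OUTSIDE_LABEL = "outside"


# ---------------------------------------------------------------------------
# fractional Brownian motion
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=64)
def _fgn_spectrum(n_steps: int, hurst: float) -> Optional[np.ndarray]:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    Returns None when the embedding is not nonnegative definite, in which
    case the caller falls back to a Cholesky factor.
    """
    k = np.arange(n_steps + 1, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * ((k + 1.0) ** h2 - 2.0 * k ** h2 + np.abs(k - 1.0) ** h2)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-9 * max(1.0, lam.max()):
        return None
    return np.clip(lam, 0.0, None)


@functools.lru_cache(maxsize=16)
def _fgn_cholesky(n_steps: int, hurst: float) -> np.ndarray:
    k = np.arange(n_steps, dtype=float)
    h2 = 2.0 * hurst
    gamma = 0.5 * (np.abs(k + 1) ** h2 - 2.0 * k ** h2 + np.abs(k - 1) ** h2)
    cov = gamma[np.abs(np.subtract.outer(np.arange(n_steps),
                                         np.arange(n_steps)))]
    # tiny jitter guards against numerically semidefinite covariances
    cov[np.diag_indices_from(cov)] += 1e-12
    return np.linalg.cholesky(cov)


def _fgn(n_tracks: int, n_steps: int, hurst: float,
         rng: np.random.Generator) -> np.ndarray:
    """(n_tracks, n_steps) unit-variance fractional Gaussian noise."""
    if abs(hurst - 0.5) < 1e-12:
        return rng.standard_normal((n_tracks, n_steps))
    lam = _fgn_spectrum(n_steps, hurst)
    if lam is None:  # pragma: no cover - H <= 0.5 embeddings are PSD
        return rng.standard_normal((n_tracks, n_steps)) @ _fgn_cholesky(
            n_steps, hurst).T
    m = 2 * n_steps
    half = n_steps  # = m // 2
    v = np.zeros((n_tracks, m), dtype=complex)
    v[:, 0] = np.sqrt(lam[0]) * rng.standard_normal(n_tracks)
    v[:, half] = np.sqrt(lam[half]) * rng.standard_normal(n_tracks)
    a = rng.standard_normal((n_tracks, half - 1))
    b = rng.standard_normal((n_tracks, half - 1))
    v[:, 1:half] = np.sqrt(lam[1:half] / 2.0) * (a + 1j * b)
    v[:, half + 1:] = np.conj(v[:, half - 1:0:-1])
    x = np.fft.fft(v, axis=1) / np.sqrt(m)
    return x[:, :n_steps].real


def _fbm_paths(n_tracks: int, n_steps: int, hurst: float,
               rng: np.random.Generator) -> np.ndarray:
    """(n_tracks, n_steps + 1) standard fBm sampled at integer times,
    starting at 0, with Var[B(t)] = t**(2H)."""
    inc = _fgn(n_tracks, n_steps, hurst, rng)
    out = np.zeros((n_tracks, n_steps + 1))
    np.cumsum(inc, axis=1, out=out[:, 1:])
    return out


def _validate_fbm_params(n_frames: int, frame_interval: float, K: float,
                         alpha: float) -> None:
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    if frame_interval <= 0:
        raise ParameterError("frame_interval must be positive")
    if K < 0:
        raise ParameterError(f"K must be nonnegative, got {K}")
    if not (0.0 < alpha <= 1.0):
        raise ParameterError(f"alpha must lie in (0, 1], got {alpha}")


def generate_fbm_tracks(n_tracks: int, n_frames: int, frame_interval: float,
                        K: float, alpha: float, seed) -> List[Trajectory]:
    """Batch of independent 2-D fBm trajectories.

    Each coordinate is an independent fBm scaled so the two together give
    ``E[MSD(t)] = K * t**alpha`` (K/2 per coordinate).
    """
    _validate_fbm_params(n_frames, frame_interval, K, alpha)
    rng = np.random.default_rng(seed)
    n_steps = n_frames - 1
    scale = np.sqrt(0.5 * K * frame_interval ** alpha)
    if K == 0:
        xy = np.zeros((2, n_tracks, n_frames))
    else:
        xy = np.stack([
            scale * _fbm_paths(n_tracks, n_steps, alpha / 2.0, rng),
            scale * _fbm_paths(n_tracks, n_steps, alpha / 2.0, rng),
        ])
    frames = np.arange(n_frames)
    return [Trajectory(i, frames, xy[0, i], xy[1, i]) for i in range(n_tracks)]


def generate_fbm_track(n_frames: int, frame_interval: float, K: float,
                       alpha: float, seed) -> Trajectory:
    """Single 2-D fBm trajectory; see :func:`generate_fbm_tracks`."""
    return generate_fbm_tracks(1, n_frames, frame_interval, K, alpha, seed)[0]


def add_localization_noise(track: Trajectory, sigma: float, seed) -> Trajectory:
    """Add static localization error: iid N(0, sigma^2) per coordinate.

    Raises every ensemble-averaged TA-MSD value by ~4*sigma^2 (two
    coordinates, two noisy endpoints per squared displacement).
    """
    if sigma < 0:
        raise ParameterError("sigma must be nonnegative")
    if sigma == 0:
        return track
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(track), 2))
    return Trajectory(track.track_id, track.frames, track.x + noise[:, 0],
                      track.y + noise[:, 1], track.label)


# ---------------------------------------------------------------------------
# scene configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one synthetic cell.

    Defaults emulate the imaging conditions of the single-molecule
    experiments this generator stands in for: 130 nm pixels, ~86.7 ms
    effective frame time per channel, territories of ~1 um^2 cross-section,
    subdiffusive nucleosomes with K ~ 0.03 um^2/s^alpha and alpha ~ 0.5, and
    ~30 nm static localization error.
    """

    image_shape: Tuple[int, int] = (192, 192)
    pixel_size: float = 0.13            # um / pixel
    n_frames: int = 30
    frame_interval: float = 0.08668     # s (two alternating channels)
    n_regions: int = 24
    region_radius_mean: float = 0.56    # um -> area ~ 1 um^2
    region_radius_sd: float = 0.18      # um; site areas spread widely
    K_inside: float = 0.03              # um^2 / s^alpha
    K_outside: float = 0.03
    alpha_inside: float = 0.5
    alpha_outside: float = 0.5
    loc_error_sd: float = 0.03          # um
    background_intensity: float = 100.0  # a.u.
    foreground_intensity: float = 400.0  # a.u.
    noise_scale: float = 1.0            # shot-noise sd = scale * sqrt(level)
    psf_sigma_px: float = 0.0           # optional Gaussian optical blur, px
    trace_coupling: float = 0.5         # latent-process Pearson rho
    n_tracks: int = 1000
    inside_fraction: Optional[float] = None  # None: uniform over the nucleus
    trace_length: int = 100             # time points per territory trace
    trace_interval_min: float = 3.0     # minutes between trace points
    trace_noise_sd: float = 0.05        # a.u. on rescaled-intensity scale
    motion_blur_samples: int = 1        # >1 averages positions within a frame
    confine_inside: bool = False        # reflect inside tracks at the edge
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ParameterError("pixel_size and frame_interval must be > 0")
        for name in ("alpha_inside", "alpha_outside"):
            a = getattr(self, name)
            if not (0.0 < a <= 1.0):
                raise ParameterError(f"{name} must lie in (0, 1], got {a}")
        if self.K_inside < 0 or self.K_outside < 0:
            raise ParameterError("K must be nonnegative")
        if self.loc_error_sd < 0:
            raise ParameterError("loc_error_sd must be nonnegative")
        if abs(self.trace_coupling) > 1:
            raise ParameterError("|trace_coupling| must be <= 1")
        if self.inside_fraction is not None \
                and not (0.0 <= self.inside_fraction <= 1.0):
            raise ParameterError("inside_fraction must lie in [0, 1]")
        if self.motion_blur_samples < 1:
            raise ParameterError("motion_blur_samples must be >= 1")


@dataclass
class Territory:
    """Ground-truth disk-like enriched region."""
    index: int
    center: np.ndarray       # (row, col) in pixels
    radius_px: float
    channel: str             # which Fab channel it is enriched in


@dataclass
class SyntheticScene:
    config: SceneConfig
    nucleus_mask: np.ndarray
    region_masks: Dict[str, np.ndarray]   # per Fab channel
    territories: List[Territory]
    channel_stacks: Dict[str, np.ndarray]  # (n_frames, rows, cols) float
    trajectories: TrajectorySet
    region_traces: list

    @property
    def combined_region_mask(self) -> np.ndarray:
        out = np.zeros(self.nucleus_mask.shape, dtype=bool)
        for m in self.region_masks.values():
            out |= m
        return out


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _ellipse_mask(shape: Tuple[int, int], fraction: float = 0.84) -> np.ndarray:
    """Pixel j covers [j, j+1) (floor containment); its centre is j + 0.5."""
    rows, cols = shape
    cy, cx = rows / 2.0, cols / 2.0
    a, b = fraction * rows / 2.0, fraction * cols / 2.0
    yy, xx = np.mgrid[0:rows, 0:cols]
    return (((yy + 0.5 - cy) / a) ** 2
            + ((xx + 0.5 - cx) / b) ** 2) <= 1.0


def _reflect_in_disk(pos: np.ndarray, center: np.ndarray,
                     radius: float) -> np.ndarray:
    """Mirror positions that left a disk back across its boundary."""
    d = np.linalg.norm(pos - center, axis=-1)
    out = d > radius
    if np.any(out):
        unit = (pos[out] - center) / d[out, None]
        dnew = np.minimum(2.0 * radius - d[out], radius)
        dnew = np.maximum(dnew, 0.0)
        pos = pos.copy()
        pos[out] = center + unit * dnew[:, None]
    return pos


def _reflect_in_ellipse(pos: np.ndarray, center: np.ndarray,
                        axes: np.ndarray) -> np.ndarray:
    """Approximate reflection at an axis-aligned ellipse (normalized radius)."""
    u = (pos - center) / axes
    rho = np.linalg.norm(u, axis=-1)
    out = rho > 1.0
    if np.any(out):
        factor = np.clip(2.0 - rho[out], 0.0, 1.0) / rho[out]
        pos = pos.copy()
        pos[out] = center + u[out] * factor[:, None] * axes
    return pos


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

def _place_territories(config: SceneConfig, nucleus: np.ndarray,
                       rng: np.random.Generator,
                       max_attempts: int = 2000) -> List[Territory]:
    rows, cols = config.image_shape
    cy, cx = rows / 2.0, cols / 2.0
    a, b = 0.84 * rows / 2.0, 0.84 * cols / 2.0
    territories: List[Territory] = []
    for i in range(config.n_regions):
        radius_um = max(rng.normal(config.region_radius_mean,
                                   config.region_radius_sd),
                        2.0 * config.pixel_size)
        r_px = radius_um / config.pixel_size
        for attempt in range(max_attempts):
            # uniform in the nucleus, margin so the disk fits inside
            row = rng.uniform(0, rows)
            col = rng.uniform(0, cols)
            if (((row - cy) / (a - r_px - 1)) ** 2
                    + ((col - cx) / (b - r_px - 1)) ** 2) > 1.0:
                continue
            # distinct sites must stay resolvable after the 1-px dilation
            # of the cleanup step, hence the 3-px separation buffer
            ok = all(np.hypot(row - t.center[0], col - t.center[1])
                     > r_px + t.radius_px + 3.0 for t in territories)
            if ok:
                channel = CHANNELS[i % 2]  # alternate h3k27ac / ser5ph
                territories.append(Territory(i, np.array([row, col]),
                                             r_px, channel))
                break
        else:
            raise ConfigurationError(
                f"could not place territory {i} without overlap after "
                f"{max_attempts} attempts; reduce n_regions or radii")
    return territories


def _territory_masks(config: SceneConfig,
                     territories: Sequence[Territory]) -> Dict[str, np.ndarray]:
    rows, cols = config.image_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    masks = {ch: np.zeros((rows, cols), dtype=bool) for ch in CHANNELS[:2]}
    owner = np.full((rows, cols), -1, dtype=int)
    for t in territories:
        disk = (yy + 0.5 - t.center[0]) ** 2 \
            + (xx + 0.5 - t.center[1]) ** 2 <= t.radius_px ** 2
        masks[t.channel] |= disk
        owner[disk] = t.index
    return masks, owner


def _spawn_group(n: int, n_frames: int, frame_interval: float, K: float,
                 alpha: float, starts: np.ndarray, reflect,
                 rng: np.random.Generator,
                 blur_samples: int = 1) -> np.ndarray:
    """Simulate n confined fBm walkers from given starts.

    Returns positions (n, n_frames, 2) in um.  ``reflect`` maps a position
    array back into the allowed domain.  When ``blur_samples > 1`` the walk
    is simulated on a finer grid and positions are averaged within each
    frame (motion blur / dynamic error).
    """
    if n == 0:
        return np.zeros((0, n_frames, 2))
    sub = int(blur_samples)
    n_sub = n_frames * sub
    dt = frame_interval / sub
    if K == 0:
        inc = np.zeros((n, n_sub - 1, 2))
    else:
        scale = np.sqrt(0.5 * K * dt ** alpha)
        inc = np.stack([
            scale * _fgn(n, n_sub - 1, alpha / 2.0, rng),
            scale * _fgn(n, n_sub - 1, alpha / 2.0, rng),
        ], axis=-1)
    fine = np.empty((n, n_sub, 2))
    fine[:, 0] = reflect(starts.copy())
    for j in range(1, n_sub):
        fine[:, j] = reflect(fine[:, j - 1] + inc[:, j - 1])
    if sub == 1:
        return fine
    return fine.reshape(n, n_frames, sub, 2).mean(axis=2)


def generate_scene(config: SceneConfig,
                   render_images: bool = True) -> SyntheticScene:
    """Build a complete synthetic cell from a :class:`SceneConfig`.

    A trajectory's (K, alpha) is set by where it spawns: tracks starting
    inside a territory move with the inside parameters, all others with the
    outside parameters.  By default tracks are free fBm reflected only at
    the nucleus boundary, so the enrichment masks select tracks with the
    same residence statistics a randomized null mask sees -- the premise of
    the randomized-mask control.  With ``confine_inside=True`` inside
    tracks are instead reflected at their territory edge (a hard-territory
    model; note it removes mask-capture selection for inside tracks, so
    real-vs-null contrasts acquire a positive bias).  Setting
    ``render_images=False`` skips the image stacks for statistics-only
    workloads.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.image_shape
    nucleus = _ellipse_mask(config.image_shape)
    territories = _place_territories(config, nucleus, rng)
    region_masks, owner_map = _territory_masks(config, territories)

    px = config.pixel_size
    nuc_center = np.array([cols / 2.0, rows / 2.0]) * px
    nuc_axes = np.array([0.84 * cols / 2.0 - 1.0,
                         0.84 * rows / 2.0 - 1.0]) * px

    def _nucleus_reflect(p):
        return _reflect_in_ellipse(p, nuc_center, nuc_axes)

    # ---- spawn sites and ground-truth owners ----
    n_tracks = config.n_tracks
    if config.inside_fraction is None or not territories:
        nuc_pixels = np.argwhere(nucleus)
        idx = rng.integers(0, len(nuc_pixels), size=n_tracks)
        spawn_pix = nuc_pixels[idx]
        starts = (spawn_pix[:, ::-1]
                  + rng.uniform(0.0, 1.0, (n_tracks, 2))) * px
        # ground truth by the spawn pixel's territory, consistent with the
        # floor-containment rule used for mask assignment downstream
        owner = owner_map[spawn_pix[:, 0], spawn_pix[:, 1]]
    else:
        n_inside = int(round(config.inside_fraction * n_tracks))
        owner = np.full(n_tracks, -1)
        owner[:n_inside] = rng.integers(0, len(territories), size=n_inside)
        starts = np.zeros((n_tracks, 2))
        for i in range(n_inside):
            terr = territories[owner[i]]
            r = max(terr.radius_px - 1.0, 1.0) * px
            theta = rng.uniform(0, 2 * np.pi)
            rad = r * np.sqrt(rng.uniform())
            starts[i] = terr.center[::-1] * px + [rad * np.cos(theta),
                                                  rad * np.sin(theta)]
        combined = np.zeros((rows, cols), dtype=bool)
        for m in region_masks.values():
            combined |= m
        free = np.argwhere(nucleus & ~combined)
        idx = rng.integers(0, len(free), size=n_tracks - n_inside)
        starts[n_inside:] = (free[idx][:, ::-1] + rng.uniform(
            0.0, 1.0, (n_tracks - n_inside, 2))) * px

    # ---- simulate per mobility group ----
    positions = np.zeros((n_tracks, config.n_frames, 2))
    inside_sel = owner >= 0
    if inside_sel.any():
        if config.confine_inside:
            for ti, terr in enumerate(territories):
                sel = np.where(owner == ti)[0]
                if sel.size == 0:
                    continue
                center = terr.center[::-1] * px
                radius = max(terr.radius_px - 1.0, 1.0) * px
                grp_starts = _reflect_in_disk(starts[sel], center, radius)
                positions[sel] = _spawn_group(
                    sel.size, config.n_frames, config.frame_interval,
                    config.K_inside, config.alpha_inside, grp_starts,
                    lambda p, c=center, r=radius: _reflect_in_disk(p, c, r),
                    rng, config.motion_blur_samples)
        else:
            sel = np.where(inside_sel)[0]
            positions[sel] = _spawn_group(
                sel.size, config.n_frames, config.frame_interval,
                config.K_inside, config.alpha_inside, starts[sel],
                _nucleus_reflect, rng, config.motion_blur_samples)
    sel_out = np.where(~inside_sel)[0]
    if sel_out.size:
        positions[sel_out] = _spawn_group(
            sel_out.size, config.n_frames, config.frame_interval,
            config.K_outside, config.alpha_outside, starts[sel_out],
            _nucleus_reflect, rng, config.motion_blur_samples)

    trajectories: List[Trajectory] = []
    frames = np.arange(config.n_frames)
    for i in range(n_tracks):
        label = OUTSIDE_LABEL if owner[i] < 0 \
            else int(territories[owner[i]].index)
        trajectories.append(Trajectory(i, frames, positions[i, :, 0],
                                       positions[i, :, 1], label=label))

    if config.loc_error_sd > 0:
        noise_seed = rng.integers(0, 2 ** 31)
        trajectories = [
            add_localization_noise(t, config.loc_error_sd, noise_seed + k)
            for k, t in enumerate(trajectories)]

    # ---- image stacks ----
    channel_stacks: Dict[str, np.ndarray] = {}
    if render_images:
        from scipy.ndimage import gaussian_filter

        for ch in CHANNELS:
            base = np.where(nucleus, config.background_intensity, 0.0)
            if ch in region_masks:
                base = base + np.where(region_masks[ch],
                                       config.foreground_intensity
                                       - config.background_intensity, 0.0)
            else:  # H2B: uniform nuclear signal, brighter than background
                base = np.where(nucleus, 2.0 * config.background_intensity,
                                0.0)
            if config.psf_sigma_px > 0:
                base = gaussian_filter(base, config.psf_sigma_px)
            sd = config.noise_scale * np.sqrt(np.clip(base, 0.0, None))
            stack = base[None] + rng.normal(
                0.0, 1.0, (config.n_frames, rows, cols)) * sd[None]
            channel_stacks[ch] = np.clip(stack, 0.0, None)

    traces = generate_region_traces(
        max(len(territories), 0), config.trace_length, config.trace_coupling,
        config.trace_noise_sd, seed=int(rng.integers(0, 2 ** 31)),
        interval_min=config.trace_interval_min)

    return SyntheticScene(config, nucleus, region_masks, territories,
                          channel_stacks,
                          TrajectorySet(trajectories, config.frame_interval,
                                        config.pixel_size,
                                        cell_id=config.seed),
                          traces)


# ---------------------------------------------------------------------------
# territory intensity traces
# ---------------------------------------------------------------------------

def generate_region_traces(n_tracks: int, length: int, coupling: float,
                           noise_sd: float, seed,
                           interval_min: float = 3.0,
                           amplitude: float = 0.3,
                           smooth_sigma: float = 2.0) -> list:
    """Minutes-cadence three-channel intensity traces with known coupling.

    Each track derives from smooth latent Gaussian processes built by
    filtering iid noise with one shared Gaussian kernel and standardized to
    unit variance; the two Fab channels ("h3k27ac", "ser5ph") are coupled
    so that the *observed* traces (including the iid measurement noise)
    have population Pearson correlation exactly ``coupling`` -- the latent
    coupling is inflated by the noise attenuation factor
    ``1 + noise_sd**2 / amplitude**2``.  Couplings unreachable at the
    requested noise level are rejected.  The H2B channel mixes the H3K27ac
    latent with an independent one (nucleosome density co-varies with
    acetylation but is not a copy of it).
    """
    from scipy.ndimage import gaussian_filter1d

    from .regions import RegionTrack

    if abs(coupling) > 1:
        raise ParameterError("|coupling| must be <= 1")
    if length < 2:
        raise ParameterError("length must be >= 2")
    rng = np.random.default_rng(seed)
    times = np.arange(length) * interval_min
    tracks = []
    pad = int(4 * smooth_sigma)
    # population sd of the smoothed unit-variance noise: ||kernel||_2
    impulse = np.zeros(2 * pad + 1)
    impulse[pad] = 1.0
    kernel_norm = float(np.sqrt(np.sum(
        gaussian_filter1d(impulse, smooth_sigma) ** 2)))
    attenuation = 1.0 + (noise_sd / amplitude) ** 2
    latent_coupling = coupling * attenuation
    if abs(latent_coupling) > 1.0:
        raise ParameterError(
            f"|coupling|={abs(coupling):.3f} unreachable with noise_sd="
            f"{noise_sd} at amplitude {amplitude}")
    for i in range(n_tracks):
        z = rng.standard_normal((3, length + 2 * pad))
        z = gaussian_filter1d(z, smooth_sigma, axis=1, mode="wrap")
        z = z[:, pad:pad + length] / kernel_norm
        # identical filtering keeps the cross-channel correlation exact
        a = z[0]
        b = latent_coupling * z[0] \
            + np.sqrt(1.0 - latent_coupling ** 2) * z[1]
        h = 0.6 * z[0] + 0.8 * z[2]
        traces = {
            "h3k27ac": amplitude * a,
            "ser5ph": amplitude * b,
            "h2b": amplitude * h,
        }
        if noise_sd > 0:
            for ch in traces:
                traces[ch] = traces[ch] + rng.normal(0, noise_sd, length)
        tracks.append(RegionTrack(
            track_id=i, times=times.copy(),
            centroids=np.zeros((length, 2)),
            areas=np.full(length, np.nan),
            traces=traces,
            interpolated=np.zeros(length, dtype=bool)))
    return tracks


# ---------------------------------------------------------------------------
# Rouse bead-spring reference chains
# ---------------------------------------------------------------------------

def rouse_monomer_tracks(n_chains: int, n_beads: int = 32,
                         n_frames: int = 11, sample_interval: float = 2.0,
                         dt: float = 0.02, spring_constant: float = 1.0,
                         kT: float = 1.0, friction: float = 1.0,
                         seed=0) -> TrajectorySet:
    """Middle-monomer tracks of free-draining overdamped Rouse chains.

    Chains start from exact equilibrium (iid Gaussian bonds with variance
    kT/k per coordinate) and evolve by Euler-Maruyama integration of
    ``zeta dx_i = k (x_{i+1} - 2 x_i + x_{i-1}) dt + sqrt(2 zeta kT) dW``.
    At lag times between the fastest mode time ``zeta/(4k)`` and the Rouse
    time, monomer MSD grows as t**(1/2); ``sample_interval`` should sit in
    that window.  Units are reduced (kT = zeta = 1 by default); only the
    MSD exponent is meaningful downstream.
    """
    if n_beads < 3:
        raise ParameterError("n_beads must be >= 3")
    rng = np.random.default_rng(seed)
    sub = max(int(round(sample_interval / dt)), 1)
    dt = sample_interval / sub
    bond_sd = np.sqrt(kT / spring_constant)
    bonds = rng.normal(0.0, bond_sd, (n_chains, n_beads - 1, 2))
    x = np.concatenate([np.zeros((n_chains, 1, 2)),
                        np.cumsum(bonds, axis=1)], axis=1)
    noise_sd = np.sqrt(2.0 * kT * dt / friction)
    mobility = spring_constant * dt / friction
    mid = n_beads // 2
    out = np.empty((n_chains, n_frames, 2))
    out[:, 0] = x[:, mid]
    for f in range(1, n_frames):
        for _ in range(sub):
            lap = np.empty_like(x)
            lap[:, 1:-1] = x[:, 2:] - 2.0 * x[:, 1:-1] + x[:, :-2]
            lap[:, 0] = x[:, 1] - x[:, 0]
            lap[:, -1] = x[:, -2] - x[:, -1]
            x += mobility * lap + noise_sd * rng.standard_normal(x.shape)
        out[:, f] = x[:, mid]
    frames = np.arange(n_frames)
    tracks = [Trajectory(i, frames, out[i, :, 0], out[i, :, 1])
              for i in range(n_chains)]
    return TrajectorySet(tracks, frame_interval=sample_interval,
                         pixel_size=1.0, cell_id="rouse")
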