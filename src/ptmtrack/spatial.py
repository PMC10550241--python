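"""Spatial auto- and cross-correlation of nuclear channel images.

Images are mean-subtracted over an analysis mask (nucleus minus nucleoli,
supplied by the caller), zeroed outside it, and cross-correlated with the
full linear correlation surface; radial averaging over rings of fixed pixel
width and normalization by the zero-shift value yield a 1-D profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, ParameterError


@dataclass
class RadialCorrelation:
    radii: np.ndarray        # um; radii[0] = 0 (the zero-shift value itself)
    correlation: np.ndarray  # normalized so correlation[0] = 1
    channel_pair: Tuple[str, str] = ("", "")


def spatial_correlation(img_a: np.ndarray, img_b: np.ndarray,
                        analysis_mask: np.ndarray) -> np.ndarray:
    """Full 2-D linear cross-correlation of two masked, mean-subtracted
    images.  Returns a (2R-1, 2C-1) surface; zero shift at its center."""
    a = np.asarray(img_a, dtype=float)
    b = np.asarray(img_b, dtype=float)
    mask = np.asarray(analysis_mask, dtype=bool)
    if not (a.shape == b.shape == mask.shape):
        raise ParameterError("image and mask shapes differ")
    if not mask.any():
        raise DegenerateInputError("empty analysis mask")
    a0 = np.where(mask, a - a[mask].mean(), 0.0)
    b0 = np.where(mask, b - b[mask].mean(), 0.0)
    return signal.correlate(a0, b0, mode="full", method="fft")


def radial_average(corr_map: np.ndarray, ring_width: int = 2,
                   pixel_size: float = 1.0,
                   channel_pair: Tuple[str, str] = ("", "")
                   ) -> RadialCorrelation:
    """Ring-averaged profile of a correlation surface, normalized at r = 0.

    Ring k (k >= 1) collects shifts with radial distance in
    (ring_width*(k-1), ring_width*k]; its nominal radius is the ring
    center.  The r = 0 entry is the zero-shift value itself.
    """
    corr_map = np.asarray(corr_map, dtype=float)
    rows, cols = corr_map.shape
    if rows % 2 == 0 or cols % 2 == 0:
        raise ParameterError("correlation surface must have odd dimensions")
    center = corr_map[rows // 2, cols // 2]
    if center == 0:
        raise DegenerateInputError("zero-shift correlation is zero")
    yy, xx = np.mgrid[0:rows, 0:cols]
    dist = np.hypot(yy - rows // 2, xx - cols // 2)
    n_rings = int(np.ceil(dist.max() / ring_width))
    radii = [0.0]
    values = [1.0]
    for k in range(1, n_rings + 1):
        sel = (dist > ring_width * (k - 1)) & (dist <= ring_width * k)
        if not sel.any():
            continue
        radii.append((ring_width * (k - 0.5)) * pixel_size)
        values.append(float(corr_map[sel].mean()) / center)
    return RadialCorrelation(np.asarray(radii), np.asarray(values),
                             channel_pair)


def radial_cross_correlation(img_a: np.ndarray, img_b: np.ndarray,
                             analysis_mask: np.ndarray,
                             ring_width: int = 2, pixel_size: float = 1.0,
                             channel_pair: Tuple[str, str] = ("", "")
                             ) -> RadialCorrelation:
    """Convenience wrapper: correlation surface then radial averaging."""
    surface = spatial_correlation(img_a, img_b, analysis_mask)
    return radial_average(surface, ring_width, pixel_size, channel_pair)
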