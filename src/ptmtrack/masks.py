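"""Segmentation of PTM-enriched subnuclear territories.

A nuclear image is min-max normalized to [0, 1] over nuclear pixels and
binarized with a local adaptive threshold evaluated per pixel over an
odd-sided square window,

    I_LT = a * <I_n> + b * sigma_I + g,

where ``<I_n>`` and ``sigma_I`` are the windowed mean and standard
deviation.  Pixels outside the nucleus contribute 0 to the window
statistics, mirroring an analysis in which the hand-drawn nuclear mask is
multiplied into the image before thresholding.  The defaults (21x21 window,
a = 0.94, b = 0.6, g = 0.05) pick out bright blobs smaller than the window;
note this a/b/g parameterization is unrelated to the anomalous-diffusion
exponent alpha used elsewhere in the package.

Cleanup removes connected components below a size cutoff (8-connectivity)
and dilates the survivors by one pixel.  Morphology-preserving null masks
are produced by rigidly translating every component by an independent
uniform integer vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, ParameterError

#: 8-connectivity structuring element for component labeling.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class BinarizeParams:
    """Local-adaptive-threshold and cleanup parameters."""

    window_size: int = 21          # odd side; neighborhood n = side**2 = 441
    a_weight: float = 0.94         # weight of the windowed mean
    b_weight: float = 0.6          # weight of the windowed SD
    g_offset: float = 0.05         # additive offset
    min_component_size: int = 10   # pixels; strictly smaller is removed
    dilation_radius: int = 1       # pixels; square structuring element

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ParameterError("window_size must be a positive odd integer")
        for name in ("a_weight", "b_weight", "g_offset"):
            if not np.isfinite(getattr(self, name)):
                raise ParameterError(f"{name} must be finite")
        if self.min_component_size < 0 or self.dilation_radius < 0:
            raise ParameterError("sizes/radii must be nonnegative")

    @property
    def window_pixels(self) -> int:
        return self.window_size ** 2


@dataclass
class MaskSeries:
    """Time-ordered binary masks with the frame range each one governs.

    ``epoch_frames[i] = (start, stop)`` means masks[i] applies to movie
    frames start <= f < stop; epochs must partition the covered range.
    """

    masks: List[np.ndarray]
    epoch_frames: List[Tuple[int, int]]
    pixel_size: float

    def __post_init__(self) -> None:
        if len(self.masks) != len(self.epoch_frames):
            raise ParameterError("one epoch range per mask is required")
        if not self.masks:
            raise ParameterError("MaskSeries requires at least one mask")
        shape = self.masks[0].shape
        if any(m.shape != shape for m in self.masks):
            raise ParameterError("all masks must share one shape")
        last = None
        for start, stop in self.epoch_frames:
            if stop <= start:
                raise ParameterError("empty epoch range")
            if last is not None and start != last:
                raise ParameterError("epochs must partition the frame range")
            last = stop

    @property
    def frame_range(self) -> Tuple[int, int]:
        return self.epoch_frames[0][0], self.epoch_frames[-1][1]

    def mask_for_frame(self, frame: int) -> np.ndarray:
        for (start, stop), mask in zip(self.epoch_frames, self.masks):
            if start <= frame < stop:
                return mask
        raise ParameterError(f"frame {frame} outside all mask epochs")

    @staticmethod
    def static(mask: np.ndarray, n_frames: int,
               pixel_size: float) -> "MaskSeries":
        """A single mask governing every frame of a movie."""
        return MaskSeries([mask], [(0, int(n_frames))], pixel_size)


def local_adaptive_binarize(image: np.ndarray, nucleus: np.ndarray,
                            params: BinarizeParams = BinarizeParams()
                            ) -> np.ndarray:
    """Adaptive threshold of a nuclear image; returns a boolean mask.

    A pixel is foreground iff it lies in the nucleus and its normalized
    value strictly exceeds a*<I_n> + b*sigma_I + g over its window.
    """
    image = np.asarray(image, dtype=float)
    nucleus = np.asarray(nucleus, dtype=bool)
    if image.shape != nucleus.shape:
        raise ParameterError("image and nucleus mask shapes differ")
    if not nucleus.any():
        raise DegenerateInputError("empty nucleus mask")
    vals = image[nucleus]
    vmin, vmax = float(vals.min()), float(vals.max())
    if vmax == vmin:
        raise DegenerateInputError("constant nuclear image: no dynamic range")
    norm = np.where(nucleus, (image - vmin) / (vmax - vmin), 0.0)
    size = params.window_size
    mean = ndimage.uniform_filter(norm, size=size, mode="constant", cval=0.0)
    meansq = ndimage.uniform_filter(norm ** 2, size=size, mode="constant",
                                    cval=0.0)
    sd = np.sqrt(np.clip(meansq - mean ** 2, 0.0, None))
    threshold = params.a_weight * mean + params.b_weight * sd + params.g_offset
    return (norm > threshold) & nucleus


def clean_mask(mask: np.ndarray,
               params: BinarizeParams = BinarizeParams()) -> np.ndarray:
    """Remove components below the size cutoff, then dilate the rest."""
    mask = np.asarray(mask, dtype=bool)
    if params.min_component_size > 1 and mask.any():
        labeled, _ = ndimage.label(mask, structure=_STRUCT8)
        sizes = np.bincount(labeled.ravel())
        keep = sizes >= params.min_component_size
        keep[0] = False
        mask = keep[labeled]
    if params.dilation_radius > 0 and mask.any():
        # unit Euclidean ball on the grid ("1 pixel in all directions");
        # a square footprint would overshoot disk-like regions at corners
        footprint = ndimage.generate_binary_structure(2, 1)
        mask = ndimage.binary_dilation(mask, structure=footprint,
                                       iterations=params.dilation_radius)
    return mask


@dataclass
class RandomizedMask:
    """Null mask plus the bookkeeping needed to audit it."""

    mask: np.ndarray
    shifts: List[Tuple[int, int]]       # (d_row, d_col) per component
    component_areas: List[int]
    n_clipped: int                      # components kept at a clipped draw

    def __iter__(self):  # allows ``mask, info = randomize_mask(...)`` style
        yield self.mask
        yield self


def randomize_mask(mask: np.ndarray, nucleus: Optional[np.ndarray] = None,
                   max_shift: int = 20, seed=None,
                   max_attempts: int = 100) -> RandomizedMask:
    """Rigidly translate each connected component by a random vector.

    Every 8-connected component is shifted by an independent integer vector
    drawn uniformly from [-max_shift, max_shift]^2.  Draws that would push a
    component outside the image bounds are redrawn up to ``max_attempts``
    times, after which the last candidate is kept with out-of-bounds pixels
    clipped (counted in ``n_clipped``).  The output is the union of the
    shifted components, so component count and areas are preserved up to
    overlap between shifted components.
    """
    mask = np.asarray(mask, dtype=bool)
    if max_shift < 0:
        raise ParameterError("max_shift must be nonnegative")
    rng = np.random.default_rng(seed)
    labeled, n_comp = ndimage.label(mask, structure=_STRUCT8)
    out = np.zeros_like(mask)
    shifts: List[Tuple[int, int]] = []
    areas: List[int] = []
    n_clipped = 0
    rows, cols = mask.shape
    for comp in range(1, n_comp + 1):
        coords = np.argwhere(labeled == comp)
        areas.append(len(coords))
        chosen = None
        for _ in range(max_attempts):
            d = rng.integers(-max_shift, max_shift + 1, size=2)
            moved = coords + d
            if (moved[:, 0].min() >= 0 and moved[:, 1].min() >= 0
                    and moved[:, 0].max() < rows and moved[:, 1].max() < cols):
                chosen = (d, moved, False)
                break
        if chosen is None:
            d = rng.integers(-max_shift, max_shift + 1, size=2)
            moved = coords + d
            inside = ((moved[:, 0] >= 0) & (moved[:, 0] < rows)
                      & (moved[:, 1] >= 0) & (moved[:, 1] < cols))
            chosen = (d, moved[inside], True)
            n_clipped += 1
        d, moved, _ = chosen
        shifts.append((int(d[0]), int(d[1])))
        out[moved[:, 0], moved[:, 1]] = True
    return RandomizedMask(out, shifts, areas, n_clipped)


@dataclass(frozen=True)
class OverlapStats:
    intersection_fraction: float   # |A & B| / |nucleus|
    fraction_a: float              # |A| / |nucleus|
    fraction_b: float              # |B| / |nucleus|
    jaccard: float                 # |A & B| / |A | B|; 1.0 if both empty


def mask_overlap_stats(mask_a: np.ndarray, mask_b: np.ndarray,
                       nucleus: np.ndarray) -> OverlapStats:
    """Nucleus-normalized overlap fractions and the Jaccard index."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    nucleus = np.asarray(nucleus, dtype=bool)
    if not (a.shape == b.shape == nucleus.shape):
        raise ParameterError("mask shapes differ")
    n_nuc = int(nucleus.sum())
    if n_nuc == 0:
        raise DegenerateInputError("empty nucleus mask")
    inter = int((a & b).sum())
    union = int((a | b).sum())
    return OverlapStats(
        intersection_fraction=inter / n_nuc,
        fraction_a=int(a.sum()) / n_nuc,
        fraction_b=int(b.sum()) / n_nuc,
        jaccard=(inter / union) if union else 1.0,
    )
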