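"""Core trajectory containers.

Positions are always stored in micrometres, frames as integer indices into the
movie of the channel the molecules were imaged in.  The coordinate convention
is: origin at the centre of image pixel (0, 0), row index = y, column = x,
pixel indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ParameterError


@dataclass
class Trajectory:
    """A single-particle track in physical units.

    Attributes
    ----------
    track_id:
        Identifier, unique within its :class:`TrajectorySet`.
    frames:
        Strictly increasing integer frame indices.
    x, y:
        Positions in micrometres.
    label:
        Optional ground-truth or assigned region label (e.g. ``"inside"``,
        ``"outside"`` or a territory index).
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    label: Optional[object] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.frames.size < 1:
            raise ParameterError("trajectory must contain at least one point")
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ParameterError("frames, x and y must have equal length")
        if self.frames.size > 1 and np.any(np.diff(self.frames) <= 0):
            raise ParameterError(
                f"track {self.track_id}: frames must be strictly increasing"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ParameterError(f"track {self.track_id}: non-finite position")

    def __len__(self) -> int:
        return int(self.frames.size)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of (x, y) positions in micrometres."""
        return np.column_stack([self.x, self.y])

    def truncate(self, n_frames: int) -> "Trajectory":
        """First ``n_frames`` points (used to curb aging bias in MSDs)."""
        n = min(int(n_frames), len(self))
        return Trajectory(self.track_id, self.frames[:n], self.x[:n],
                          self.y[:n], self.label)

    def is_consecutive(self) -> bool:
        return len(self) < 2 or bool(np.all(np.diff(self.frames) == 1))


@dataclass
class TrajectorySet:
    """Tracks sharing one acquisition (frame interval, pixel size, cell)."""

    trajectories: Sequence[Trajectory]
    frame_interval: float  # seconds
    pixel_size: float  # micrometres per pixel
    cell_id: object = None

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ParameterError("frame_interval must be positive")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        self.trajectories = list(self.trajectories)

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)
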