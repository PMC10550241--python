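"""File formats: track tables (CSV / TrackMate-style XML), masks and image
stacks (TIFF), scene bundles, and YAML run configuration."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
import tifffile
import yaml
from lxml import etree

from .errors import ParameterError, ParseError
from .masks import MaskSeries
from .tracks import Trajectory, TrajectorySet

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


# ---------------------------------------------------------------------------
# track tables
# ---------------------------------------------------------------------------

def write_tracks(tracks: TrajectorySet, path) -> None:
    rows = []
    for t in tracks:
        label = "" if t.label is None else t.label
        for f, x, y in zip(t.frames, t.x, t.y):
            rows.append((t.track_id, int(f), float(x), float(y), label))
    pd.DataFrame(rows, columns=TRACK_COLUMNS + ["label"]).to_csv(
        path, index=False, float_format="%.9f")


def _tracks_from_dataframe(df: pd.DataFrame, frame_interval: float,
                           pixel_size: float, cell_id=None) -> TrajectorySet:
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"track table missing columns: {missing}")
    if df[["track_id", "frame"]].duplicated().any():
        dup = df[df[["track_id", "frame"]].duplicated()].index[0]
        raise ParseError(f"duplicate (track_id, frame) pair at row {dup}")
    trajectories = []
    has_label = "label" in df.columns
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=np.int64)
        label = None
        if has_label:
            lab = grp["label"].iloc[0]
            label = None if (pd.isna(lab) or lab == "") else lab
        try:
            trajectories.append(Trajectory(
                tid, frames, grp["x_um"].to_numpy(float),
                grp["y_um"].to_numpy(float), label=label))
        except ParameterError as exc:
            raise ParseError(f"track {tid}: {exc}") from exc
    return TrajectorySet(trajectories, frame_interval, pixel_size, cell_id)


def read_tracks_csv(path, frame_interval: float, pixel_size: float,
                    cell_id=None) -> TrajectorySet:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"cannot parse track CSV {path}: {exc}") from exc
    return _tracks_from_dataframe(df, frame_interval, pixel_size, cell_id)


def read_tracks_trackmate(path, frame_interval: float, pixel_size: float,
                          position_units: str = "um",
                          cell_id=None) -> TrajectorySet:
    """TrackMate-style XML: spots joined by track edges.

    Spots referenced by no edge are emitted as length-1 tracks.  Positions
    are converted to micrometres according to ``position_units``
    ("um" or "px").
    """
    try:
        root = etree.parse(str(path)).getroot()
    except Exception as exc:
        raise ParseError(f"cannot parse XML {path}: {exc}") from exc
    if position_units not in ("um", "px"):
        raise ParameterError("position_units must be 'um' or 'px'")
    scale = 1.0 if position_units == "um" else pixel_size
    spots: Dict[int, Tuple[int, float, float]] = {}
    for spot in root.iter("Spot"):
        sid = int(spot.get("ID"))
        spots[sid] = (int(float(spot.get("FRAME"))),
                      float(spot.get("POSITION_X")) * scale,
                      float(spot.get("POSITION_Y")) * scale)
    used = set()
    trajectories: List[Trajectory] = []
    for track in root.iter("Track"):
        ids = set()
        for edge in track.iter("Edge"):
            ids.add(int(edge.get("SPOT_SOURCE_ID")))
            ids.add(int(edge.get("SPOT_TARGET_ID")))
        if not ids:
            continue
        members = sorted(ids, key=lambda s: spots[s][0])
        frames = np.array([spots[s][0] for s in members])
        if np.any(np.diff(frames) <= 0):
            raise ParseError(
                f"track {track.get('TRACK_ID')}: non-monotone frames")
        trajectories.append(Trajectory(
            int(track.get("TRACK_ID", len(trajectories))), frames,
            np.array([spots[s][1] for s in members]),
            np.array([spots[s][2] for s in members])))
        used |= ids
    next_id = max((t.track_id for t in trajectories), default=-1) + 1
    for sid, (frame, x, y) in sorted(spots.items()):
        if sid not in used:  # orphan spot -> length-1 track
            trajectories.append(Trajectory(next_id, [frame], [x], [y]))
            next_id += 1
    return TrajectorySet(trajectories, frame_interval, pixel_size, cell_id)


def read_tracks(path, fmt: str = "csv", frame_interval: float = 1.0,
                pixel_size: float = 1.0, **kwargs) -> TrajectorySet:
    if fmt == "csv":
        return read_tracks_csv(path, frame_interval, pixel_size, **kwargs)
    if fmt == "trackmate_xml":
        return read_tracks_trackmate(path, frame_interval, pixel_size,
                                     **kwargs)
    raise ParameterError(f"unknown track format {fmt!r}")


# ---------------------------------------------------------------------------
# masks and stacks
# ---------------------------------------------------------------------------

def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8),
                     photometric="minisblack")


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_mask_series(series: MaskSeries, path_prefix: Path) -> Path:
    """Masks as a multi-page TIFF plus a CSV epoch table; returns the TIFF."""
    path_prefix = Path(path_prefix)
    tiff = path_prefix.with_suffix(".tif")
    tifffile.imwrite(tiff, np.stack(series.masks).astype(np.uint8),
                     photometric="minisblack")
    pd.DataFrame(series.epoch_frames,
                 columns=["start", "stop"]).to_csv(
        path_prefix.with_suffix(".epochs.csv"), index=False)
    return tiff


def read_mask_series(path_prefix: Path, pixel_size: float) -> MaskSeries:
    path_prefix = Path(path_prefix)
    stack = tifffile.imread(path_prefix.with_suffix(".tif")).astype(bool)
    if stack.ndim == 2:
        stack = stack[None]
    epochs = pd.read_csv(path_prefix.with_suffix(".epochs.csv"))
    return MaskSeries(list(stack),
                      [(int(r.start), int(r.stop))
                       for r in epochs.itertuples()], pixel_size)


# ---------------------------------------------------------------------------
# scene bundles and configuration
# ---------------------------------------------------------------------------

def write_scene(scene, out_dir) -> Path:
    """Persist a synthetic scene as TIFF/CSV/YAML files; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(scene.nucleus_mask, out / "nucleus_mask.tif")
    for ch, mask in scene.region_masks.items():
        write_mask(mask, out / f"region_mask_{ch}.tif")
    for ch, stack in scene.channel_stacks.items():
        write_stack(stack, out / f"stack_{ch}.tif")
    write_tracks(scene.trajectories, out / "tracks.csv")
    with open(out / "scene_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(scene.config), fh, sort_keys=True)
    rows = []
    for tr in scene.region_traces:
        for i, t in enumerate(tr.times):
            rows.append({"track_id": tr.track_id, "time_min": float(t),
                         **{ch: float(tr.traces[ch][i])
                            for ch in tr.traces}})
    pd.DataFrame(rows).to_csv(out / "region_traces.csv", index=False)
    return out


def load_scene_config(path):
    from .synthetic import SceneConfig
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "image_shape" in raw:
        raw["image_shape"] = tuple(raw["image_shape"])
    return SceneConfig(**raw)


def write_region_tracks(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for i, t in enumerate(tr.times):
            rows.append({
                "track_id": tr.track_id, "time_min": float(t),
                "centroid_row": float(tr.centroids[i][0]),
                "centroid_col": float(tr.centroids[i][1]),
                "area_px": float(tr.areas[i]),
                **{f"I_{ch}": float(tr.traces[ch][i]) for ch in tr.traces},
                "interpolated": bool(tr.interpolated[i]),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_json_report(report: dict, path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"unserializable {type(obj)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
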