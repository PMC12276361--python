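"""Track tables, trajectories, ROI geometry and shared filters.

Conventions used throughout the package:

* coordinates are stored in micrometres (μm), continuous, origin at the
  (0, 0) pixel corner of the source image; pixel-unit inputs are converted
  on read using the declared pixel size,
* frame indices are 0-based and strictly increasing within a track,
* the canonical CSV dialect is ``track_id,frame,x_um,y_um`` with optional
  ``#``-prefixed ``key=value`` metadata lines before the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["track_id", "frame", "x_um", "y_um"]

#: classes assigned by the trajectory classifier
CLASS_NAMES = ("immobile", "hybrid", "mobile")


class TrackParseError(ValueError):
    """Raised when a track table violates the format contract."""


@dataclass
class Trajectory:
    """One molecule's time-ordered 2-D localizations.

    Attributes
    ----------
    track_id : identifier
    frames : strictly increasing integer frame indices
    x, y : coordinates in μm
    frame_interval : acquisition interval Δt in seconds
    """

    track_id: object
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise TrackParseError(f"track {self.track_id}: ragged columns")
        if len(self.frames) > 1 and np.any(np.diff(self.frames) <= 0):
            raise TrackParseError(
                f"track {self.track_id}: frames must be strictly increasing"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TrackParseError(f"track {self.track_id}: non-finite coordinates")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def centroid(self) -> tuple[float, float]:
        """Time-averaged position, the ROI-membership statistic."""
        return float(np.mean(self.x)), float(np.mean(self.y))


@dataclass
class RectROI:
    """Axis-aligned rectangle, e.g. the 3-μm-wide irradiated band."""

    center: tuple[float, float]
    width: float = 3.0
    height: float = 10.0
    label: str = "inside"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("ROI width and height must be positive")

    def contains(self, x: float, y: float) -> bool:
        cx, cy = self.center
        return (abs(x - cx) <= self.width / 2) and (abs(y - cy) <= self.height / 2)


@dataclass
class TrackTable:
    """Long-format localization table plus acquisition metadata."""

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise TrackParseError(f"missing columns: {missing}")
        dup = self.data.duplicated(subset=["track_id", "frame"])
        if dup.any():
            tid = self.data.loc[dup, "track_id"].iloc[0]
            raise TrackParseError(f"duplicated (track_id, frame) in track {tid}")
        for tid, grp in self.data.groupby("track_id", sort=False):
            fr = grp["frame"].to_numpy()
            if len(fr) > 1 and np.any(np.diff(fr) <= 0):
                raise TrackParseError(
                    f"track {tid}: frames not strictly increasing"
                )

    @property
    def frame_interval(self) -> float:
        return float(self.metadata.get("frame_interval_s", 0.01))

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def track_ids(self) -> list:
        return list(self.data["track_id"].unique())

    def trajectories(self) -> Iterator[Trajectory]:
        dt = self.frame_interval
        for tid, grp in self.data.groupby("track_id", sort=False):
            yield Trajectory(
                tid,
                grp["frame"].to_numpy(),
                grp["x_um"].to_numpy(),
                grp["y_um"].to_numpy(),
                dt,
            )

    def subset(self, track_ids) -> "TrackTable":
        keep = self.data["track_id"].isin(set(track_ids))
        return TrackTable(self.data.loc[keep].reset_index(drop=True), dict(self.metadata))


def trajectories_to_table(trajs, metadata: dict | None = None) -> TrackTable:
    frames = []
    for t in trajs:
        frames.append(
            pd.DataFrame(
                {"track_id": t.track_id, "frame": t.frames, "x_um": t.x, "y_um": t.y}
            )
        )
    meta = dict(metadata or {})
    if trajs:
        meta.setdefault("frame_interval_s", trajs[0].frame_interval)
    data = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=CANONICAL_COLUMNS)
    )
    return TrackTable(data, meta)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_tracks(table: TrackTable, path) -> None:
    """Write the canonical CSV dialect with ``#`` metadata lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in table.metadata.items():
            fh.write(f"# {key}={val}\n")
        out = table.data[CANONICAL_COLUMNS].copy()
        out["x_um"] = out["x_um"].round(6)
        out["y_um"] = out["y_um"].round(6)
        out.to_csv(fh, index=False)


def read_tracks(path, metadata: dict | None = None) -> TrackTable:
    """Read a canonical track CSV.

    ``metadata`` overrides values parsed from ``#`` header lines. If the
    table declares ``unit=px``, coordinates are converted to μm using
    ``pixel_size_um`` (required in that case).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta: dict = {}
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, val = body.split("=", 1)
                meta[key.strip()] = _coerce(val.strip())
    meta.update(metadata or {})
    data = pd.read_csv(path, skiprows=skip)
    if meta.get("unit", "um") == "px":
        if "pixel_size_um" not in meta:
            raise TrackParseError("pixel-unit table requires pixel_size_um metadata")
        px = float(meta["pixel_size_um"])
        data = data.rename(columns={"x_px": "x_um", "y_px": "y_um"})
        data["x_um"] = data["x_um"] * px
        data["y_um"] = data["y_um"] * px
        meta["unit"] = "um"
    return TrackTable(data, meta)


def read_trackmate_csv(path, frame_interval: float, position_unit: str = "um",
                       pixel_size: float | None = None) -> TrackTable:
    """Convenience reader for TrackMate-style spot exports."""
    df = pd.read_csv(path)
    cols = {"TRACK_ID": "track_id", "FRAME": "frame",
            "POSITION_X": "x_um", "POSITION_Y": "y_um"}
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TrackParseError(f"missing TrackMate columns: {missing}")
    df = df[list(cols)].rename(columns=cols)
    if position_unit == "px":
        if pixel_size is None:
            raise TrackParseError("pixel-unit TrackMate table requires pixel_size")
        df[["x_um", "y_um"]] *= pixel_size
    df = df.sort_values(["track_id", "frame"]).reset_index(drop=True)
    return TrackTable(df, {"frame_interval_s": frame_interval})


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            pass
    return value


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_by_roi(table: TrackTable, roi: RectROI, mode: str = "inside") -> TrackTable:
    """Keep tracks whose time-averaged centroid lies inside (or outside) ``roi``.

    The centroid rule resolves tracks that straddle the boundary: a track
    belongs to exactly one side, so inside-mode and outside-mode partition
    any table.
    """
    if mode not in ("inside", "outside"):
        raise ValueError("mode must be 'inside' or 'outside'")
    cent = table.data.groupby("track_id", sort=False)[["x_um", "y_um"]].mean()
    inside = np.array([roi.contains(x, y) for x, y in cent.to_numpy()])
    keep_ids = cent.index[inside if mode == "inside" else ~inside]
    out = table.subset(keep_ids)
    if out.data.empty:
        logger.warning("filter_by_roi(%s): no tracks retained", mode)
    return out


def filter_by_length(table: TrackTable, min_points: int = 5) -> TrackTable:
    """Keep tracks with at least ``min_points`` localizations."""
    if min_points < 2:
        raise ValueError("min_points must be >= 2")
    sizes = table.data.groupby("track_id", sort=False).size()
    keep = sizes.index[sizes >= min_points]
    removed = len(sizes) - len(keep)
    if removed:
        logger.info("filter_by_length: removed %d of %d tracks", removed, len(sizes))
    out = table.subset(keep)
    if out.data.empty:
        logger.warning("filter_by_length: no tracks retained")
    return out
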