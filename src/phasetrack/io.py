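"""Core data types and file I/O.

A :class:`LocalizationTable` holds frame-indexed 2D point detections (the raw
input of the pipeline, as produced by any localization-microscopy software
that can export CSV), and a :class:`TrackSet` holds linked trajectories with
optional per-step phase and motion-state labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera timing and (optional) localization precision.

    frame_interval
        Seconds per frame; 0.03 s (30 ms exposure) is the default used
        throughout.
    localization_precision
        Static localization error in um (0 = ignore).
    """

    frame_interval: float = 0.03
    localization_precision: float = 0.0

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.localization_precision < 0:
            raise ValueError("localization_precision must be >= 0")


class FormatError(ValueError):
    """Raised when an input file does not have the expected columns/values."""


@dataclass
class LocalizationTable:
    """Frame-indexed 2D localizations in um, sorted by frame."""

    data: pd.DataFrame  # columns: frame, x, y[, id]
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)

    def __post_init__(self):
        required = {"frame", "x", "y"}
        if not required.issubset(self.data.columns):
            raise FormatError(f"localization table needs columns {sorted(required)}")
        if len(self.data):
            try:
                coords = self.data[["x", "y"]].to_numpy(dtype=float)
            except (TypeError, ValueError) as e:
                raise FormatError(f"non-numeric coordinates: {e}") from e
            bad = ~np.isfinite(coords).all(axis=1)
            if bad.any():
                rows = np.flatnonzero(bad)[:20].tolist()
                raise FormatError(f"non-finite coordinates at rows {rows}")
        self.data = self.data.sort_values("frame", kind="stable").reset_index(drop=True)
        self.data["frame"] = self.data["frame"].astype(np.int64)
        if (self.data["frame"] < 0).any():
            raise FormatError("negative frame indices")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy()

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def extent(self):
        """Bounding box ((xmin, ymin), (xmax, ymax)); None when empty."""
        if len(self.data) == 0:
            return None
        xy = self.xy
        return (tuple(xy.min(axis=0)), tuple(xy.max(axis=0)))


@dataclass
class Track:
    """One trajectory: strictly increasing frames plus per-step labels.

    ``phase`` holds per-step labels in {condensed, dilute, crossing} and
    ``state`` per-step motion-state labels in {L, H, unassigned}; both have
    length n_points - 1.
    """

    frames: np.ndarray
    xy: np.ndarray
    phase: Optional[np.ndarray] = None
    state: Optional[np.ndarray] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")
        n_steps = len(self.frames) - 1
        if self.phase is None:
            self.phase = np.full(n_steps, UNASSIGNED, dtype=object)
        if self.state is None:
            self.state = np.full(n_steps, UNASSIGNED, dtype=object)
        if len(self.phase) != n_steps or len(self.state) != n_steps:
            raise ValueError("label arrays must have length n_points - 1")

    @property
    def n_steps(self) -> int:
        return len(self.frames) - 1

    def displacements(self) -> np.ndarray:
        """Step magnitudes in um (consecutive localizations)."""
        return np.hypot(*np.diff(self.xy, axis=0).T)


@dataclass
class TrackSet:
    tracks: list
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def n_localizations(self) -> int:
        return sum(len(t.frames) for t in self.tracks)

    def n_links(self) -> int:
        return sum(t.n_steps for t in self.tracks)

    def displacements(self, phase: Optional[str] = None) -> np.ndarray:
        out = []
        for t in self.tracks:
            d = t.displacements()
            if phase is not None:
                d = d[np.asarray(t.phase) == phase]
            out.append(d)
        return np.concatenate(out) if out else np.empty(0)


# ---------------------------------------------------------------------------
# CSV I/O


def read_localizations(path, acquisition: Optional[AcquisitionParams] = None,
                       unit: str = "um") -> LocalizationTable:
    """Read a localization CSV with columns frame,x,y[,id].

    ``unit='nm'`` divides coordinates by 1000 (nm-dialect files).
    """
    acquisition = acquisition or AcquisitionParams()
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"frame", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if unit == "nm":
        df["x"] = df["x"] / 1000.0
        df["y"] = df["y"] / 1000.0
    elif unit != "um":
        raise ValueError("unit must be 'um' or 'nm'")
    cols = ["frame", "x", "y"] + (["id"] if "id" in df.columns else [])
    return LocalizationTable(df[cols].copy(), acquisition)


def write_localizations(table: LocalizationTable, path) -> None:
    table.data.to_csv(path, index=False, float_format="%.6f")


def read_tracks(path, acquisition: Optional[AcquisitionParams] = None) -> TrackSet:
    """Read a track CSV with columns track_id,frame,x,y[,phase,state]."""
    acquisition = acquisition or AcquisitionParams()
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = {"track_id", "frame", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    tracks = []
    for _, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        n_steps = len(g) - 1
        phase = g["phase"].to_numpy(dtype=object)[:n_steps] if "phase" in g else None
        state = g["state"].to_numpy(dtype=object)[:n_steps] if "state" in g else None
        tracks.append(Track(g["frame"].to_numpy(), g[["x", "y"]].to_numpy(),
                            phase=phase, state=state))
    return TrackSet(tracks, acquisition)


def write_tracks(trackset: TrackSet, path) -> None:
    """Write track CSV (track_id,frame,x,y,phase,state).

    Per-step labels are stored on the step's *first* localization; the last
    row of each track carries empty labels.
    """
    rows = []
    for tid, t in enumerate(trackset.tracks):
        for i in range(len(t.frames)):
            rows.append({
                "track_id": tid,
                "frame": int(t.frames[i]),
                "x": t.xy[i, 0],
                "y": t.xy[i, 1],
                "phase": t.phase[i] if i < t.n_steps else "",
                "state": t.state[i] if i < t.n_steps else "",
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def table_from_arrays(frames, x, y, ids=None,
                      acquisition: Optional[AcquisitionParams] = None) -> LocalizationTable:
    data = {"frame": np.asarray(frames), "x": np.asarray(x, float), "y": np.asarray(y, float)}
    if ids is not None:
        data["id"] = np.asarray(ids)
    return LocalizationTable(pd.DataFrame(data), acquisition or AcquisitionParams())
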