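"""Time-series containers and delimited-text I/O for gaze and hand streams.

The on-disk format is plain CSV with a required header.  Column names can be
remapped through a ``schema`` dictionary (``{canonical_name: file_column}``)
because logger formats vary between acquisition setups.  Canonical columns:

* gaze:   ``t_ms, left_x, left_y, right_x, right_y``
  (optional ``pupil_left, pupil_right, valid_left, valid_right``)
* hand:   ``t_ms, tool_x, tool_y, tool_z, cam_x, cam_y, cam_z``
  (optional ``tool_rx, tool_ry, tool_rz, cam_rx, cam_ry, cam_rz``)
* events: ``signal_id, kind, t_start_ms, t_end_ms, duration_ms, centroid_*``
* metrics: ``participant, scenario, task, FD_ms, FN, SN, SSD_ms, SSN, SSM``
* markers: ``task_index, t_start_ms, t_end_ms, completed``

Conventions fixed here and used throughout the package:

* time is milliseconds from stream start, stored as floating point;
* gaze coordinates live in a top-left-origin pixel frame (x right, y down)
  on a 1920 x 1080 display by default;
* hand coordinates are 3-D vectors in the haptic device's native length
  units, one row per sample for the tool and camera channels;
* invalid gaze samples (blinks, track loss) are retained and flagged, never
  dropped, so gap handling stays a downstream decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, SchemaError

__all__ = [
    "GazeStream",
    "HandStream",
    "read_gaze_table",
    "read_hand_table",
    "write_gaze_table",
    "write_hand_table",
    "write_event_table",
    "read_event_table",
    "write_metrics_table",
    "read_metrics_table",
    "write_markers_table",
    "read_markers_table",
]

GAZE_COLUMNS = ("t_ms", "left_x", "left_y", "right_x", "right_y")
GAZE_OPTIONAL = ("pupil_left", "pupil_right", "valid_left", "valid_right")
HAND_COLUMNS = ("t_ms", "tool_x", "tool_y", "tool_z", "cam_x", "cam_y", "cam_z")
HAND_OPTIONAL = ("tool_rx", "tool_ry", "tool_rz", "cam_rx", "cam_ry", "cam_rz")


def _check_monotone(t: np.ndarray) -> None:
    """Raise :class:`FormatError` naming the first non-increasing row."""
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise FormatError(
            f"timestamps must be strictly increasing; t[{bad[0]}]={t[bad[0]]} "
            f"followed by t[{bad[0] + 1}]={t[bad[0] + 1]}",
            row=int(bad[0]) + 2,  # 1-based, first data row is row 1
        )


def _infer_rate(t: np.ndarray) -> float:
    dt = float(np.median(np.diff(t)))
    return 1000.0 / dt


@dataclass
class GazeStream:
    """Binocular gaze samples in screen-pixel coordinates.

    Attributes
    ----------
    t : (n,) float array, milliseconds from stream start, strictly increasing.
    left, right : (n, 2) float arrays of per-eye (x, y) pixel positions.
    valid_left, valid_right : (n,) bool arrays; invalid samples may carry
        sentinel coordinates but are always flagged.
    pupil_left, pupil_right : optional (n,) arrays, arbitrary units.
    """

    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    valid_left: np.ndarray | None = None
    valid_right: np.ndarray | None = None
    pupil_left: np.ndarray | None = None
    pupil_right: np.ndarray | None = None
    nominal_rate_hz: float = 60.0
    screen_w: int = 1920
    screen_h: int = 1080

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        n = self.t.shape[0]
        if self.left.shape != (n, 2) or self.right.shape != (n, 2):
            raise ValueError("left/right must have shape (n, 2)")
        _check_monotone(self.t)
        if self.nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")
        if self.valid_left is None:
            self.valid_left = self._in_bounds(self.left)
        else:
            self.valid_left = np.asarray(self.valid_left, dtype=bool)
        if self.valid_right is None:
            self.valid_right = self._in_bounds(self.right)
        else:
            self.valid_right = np.asarray(self.valid_right, dtype=bool)

    def _in_bounds(self, pos: np.ndarray) -> np.ndarray:
        finite = np.isfinite(pos).all(axis=1)
        inb = (
            (pos[:, 0] >= 0)
            & (pos[:, 0] < self.screen_w)
            & (pos[:, 1] >= 0)
            & (pos[:, 1] < self.screen_h)
        )
        return finite & inb

    def __len__(self) -> int:
        return int(self.t.shape[0])

    @property
    def valid(self) -> np.ndarray:
        """Samples where both eyes are usable."""
        return self.valid_left & self.valid_right

    @property
    def cyclopean(self) -> np.ndarray:
        """Midpoint of the two eyes, used for event centroids."""
        return 0.5 * (self.left + self.right)

    def shifted(self, offset_ms: float) -> "GazeStream":
        return replace(self, t=self.t + offset_ms)


@dataclass
class HandStream:
    """3-D tool and camera trajectories from the haptic interface.

    ``tool`` is the dominant-hand instrument channel, ``cam`` the
    non-dominant endoscope-camera channel; both are (n, 3) arrays in the
    device's native length units.  Samples with non-finite coordinates in a
    channel are treated as gaps for that channel.
    """

    t: np.ndarray
    tool: np.ndarray
    cam: np.ndarray
    tool_rot: np.ndarray | None = None
    cam_rot: np.ndarray | None = None
    nominal_rate_hz: float = 100.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.tool = np.asarray(self.tool, dtype=float)
        self.cam = np.asarray(self.cam, dtype=float)
        n = self.t.shape[0]
        if self.tool.shape != (n, 3) or self.cam.shape != (n, 3):
            raise ValueError("tool/cam must have shape (n, 3)")
        _check_monotone(self.t)
        if self.nominal_rate_hz <= 0:
            raise ValueError("nominal_rate_hz must be positive")

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def positions(self, channel: str = "tool") -> np.ndarray:
        if channel not in ("tool", "cam", "camera"):
            raise ValueError(f"unknown hand channel {channel!r}")
        return self.tool if channel == "tool" else self.cam

    def valid_mask(self, channel: str = "tool") -> np.ndarray:
        return np.isfinite(self.positions(channel)).all(axis=1)

    def shifted(self, offset_ms: float) -> "HandStream":
        return replace(self, t=self.t + offset_ms)


def _resolve(df: pd.DataFrame, schema: dict | None, mandatory, optional):
    """Map canonical column names onto file columns; raise on missing."""
    schema = schema or {}
    out = {}
    for name in (*mandatory, *optional):
        col = schema.get(name, name)
        if col in df.columns:
            out[name] = col
        elif name in mandatory:
            raise SchemaError(
                f"mandatory column {name!r} (file column {col!r}) not found; "
                f"available: {list(df.columns)}"
            )
    return out


def read_gaze_table(
    path, schema: dict | None = None, strict: bool = True, **stream_kwargs
) -> GazeStream:
    """Read a gaze CSV into a :class:`GazeStream`.

    Missing validity columns default to "valid iff coordinates are finite
    and inside the screen bounds".  ``strict`` has no effect on gaze input
    (invalid samples are flagged, never errors); it is accepted for symmetry
    with :func:`read_hand_table`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = _resolve(df, schema, GAZE_COLUMNS, GAZE_OPTIONAL)
    if len(df) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 gaze rows, got {len(df)}")
    t = df[cols["t_ms"]].to_numpy(dtype=float)
    _check_monotone(t)
    left = df[[cols["left_x"], cols["left_y"]]].to_numpy(dtype=float)
    right = df[[cols["right_x"], cols["right_y"]]].to_numpy(dtype=float)
    kw = dict(stream_kwargs)
    for name in ("valid_left", "valid_right"):
        if name in cols:
            kw[name] = df[cols[name]].to_numpy(dtype=bool)
    for name in ("pupil_left", "pupil_right"):
        if name in cols:
            kw[name] = df[cols[name]].to_numpy(dtype=float)
    kw.setdefault("nominal_rate_hz", _infer_rate(t))
    return GazeStream(t=t, left=left, right=right, **kw)


def write_gaze_table(stream: GazeStream, path) -> None:
    data = {
        "t_ms": stream.t,
        "left_x": stream.left[:, 0],
        "left_y": stream.left[:, 1],
        "right_x": stream.right[:, 0],
        "right_y": stream.right[:, 1],
    }
    if stream.pupil_left is not None:
        data["pupil_left"] = stream.pupil_left
    if stream.pupil_right is not None:
        data["pupil_right"] = stream.pupil_right
    data["valid_left"] = stream.valid_left
    data["valid_right"] = stream.valid_right
    pd.DataFrame(data).to_csv(path, index=False)


def read_hand_table(
    path, schema: dict | None = None, strict: bool = True, **stream_kwargs
) -> HandStream:
    """Read a hand CSV into a :class:`HandStream`.

    In strict mode non-finite position coordinates are a format error; in
    permissive mode (``strict=False``) such samples are kept and exposed as
    gaps through :meth:`HandStream.valid_mask`.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    cols = _resolve(df, schema, HAND_COLUMNS, HAND_OPTIONAL)
    if len(df) < 2:
        raise InsufficientDataError(f"{path}: need at least 2 hand rows, got {len(df)}")
    t = df[cols["t_ms"]].to_numpy(dtype=float)
    _check_monotone(t)
    tool = df[[cols["tool_x"], cols["tool_y"], cols["tool_z"]]].to_numpy(dtype=float)
    cam = df[[cols["cam_x"], cols["cam_y"], cols["cam_z"]]].to_numpy(dtype=float)
    if strict:
        bad = np.nonzero(~(np.isfinite(tool).all(axis=1) & np.isfinite(cam).all(axis=1)))[0]
        if bad.size:
            raise FormatError(
                "non-finite hand coordinates in strict mode", row=int(bad[0]) + 2
            )
    kw = dict(stream_kwargs)
    if all(f"tool_r{a}" in cols for a in "xyz"):
        kw["tool_rot"] = df[[cols[f"tool_r{a}"] for a in "xyz"]].to_numpy(dtype=float)
    if all(f"cam_r{a}" in cols for a in "xyz"):
        kw["cam_rot"] = df[[cols[f"cam_r{a}"] for a in "xyz"]].to_numpy(dtype=float)
    kw.setdefault("nominal_rate_hz", _infer_rate(t))
    return HandStream(t=t, tool=tool, cam=cam, **kw)


def write_hand_table(stream: HandStream, path) -> None:
    data = {"t_ms": stream.t}
    for i, a in enumerate("xyz"):
        data[f"tool_{a}"] = stream.tool[:, i]
    for i, a in enumerate("xyz"):
        data[f"cam_{a}"] = stream.cam[:, i]
    if stream.tool_rot is not None:
        for i, a in enumerate("xyz"):
            data[f"tool_r{a}"] = stream.tool_rot[:, i]
    if stream.cam_rot is not None:
        for i, a in enumerate("xyz"):
            data[f"cam_r{a}"] = stream.cam_rot[:, i]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# derived tables (events / metrics / markers)
# ---------------------------------------------------------------------------

def write_event_table(events, path) -> None:
    """Write an :class:`~gazehand.events.EventSequence` as CSV, one row per
    interval.  Gap intervals carry NaN centroids."""
    d = events.ndim
    rows = []
    for ev in events.events:
        row = {
            "signal_id": events.signal_id,
            "kind": ev.kind,
            "t_start_ms": ev.t_start,
            "t_end_ms": ev.t_end,
            "duration_ms": ev.duration,
        }
        cen = ev.centroid if ev.centroid is not None else np.full(d, np.nan)
        for j in range(d):
            row[f"centroid_{j + 1}"] = cen[j]
        rows.append(row)
    cols = ["signal_id", "kind", "t_start_ms", "t_end_ms", "duration_ms"] + [
        f"centroid_{j + 1}" for j in range(d)
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_event_table(path):
    """Reconstruct an :class:`~gazehand.events.EventSequence` from CSV.

    The threshold provenance is not stored on disk, so ``theta_used`` of the
    returned sequence is ``None``.
    """
    from .events import EventInterval, EventSequence  # local import, no cycle at module load

    df = pd.read_csv(path, float_precision="round_trip")
    cen_cols = sorted(
        (c for c in df.columns if c.startswith("centroid_")),
        key=lambda c: int(c.split("_")[1]),
    )
    events = []
    signal_id = str(df["signal_id"].iloc[0]) if len(df) else "unknown"
    for _, row in df.iterrows():
        cen = np.array([row[c] for c in cen_cols], dtype=float)
        events.append(
            EventInterval(
                kind=str(row["kind"]),
                t_start=float(row["t_start_ms"]),
                t_end=float(row["t_end_ms"]),
                centroid=None if np.isnan(cen).all() else cen,
            )
        )
    window = (events[0].t_start, events[-1].t_end) if events else (0.0, 0.0)
    return EventSequence(
        signal_id=signal_id, events=events, theta_used=None, window=window,
        ndim=len(cen_cols),
    )


METRIC_COLUMNS = ["participant", "scenario", "task", "FD_ms", "FN", "SN", "SSD_ms", "SSN", "SSM"]


def write_metrics_table(records, path) -> None:
    """Write per-task metric records (list of MetricsRecord or DataFrame)."""
    if isinstance(records, pd.DataFrame):
        df = records[METRIC_COLUMNS]
    else:
        df = pd.DataFrame([r.as_row() for r in records], columns=METRIC_COLUMNS)
    df.to_csv(path, index=False)


def read_metrics_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"metrics table missing columns {missing}")
    return df


def write_markers_table(segments, path) -> None:
    rows = [
        {
            "task_index": s.task_index,
            "t_start_ms": s.t_start,
            "t_end_ms": s.t_end,
            "completed": s.completed,
        }
        for s in segments
    ]
    pd.DataFrame(rows, columns=["task_index", "t_start_ms", "t_end_ms", "completed"]).to_csv(
        path, index=False
    )


def read_markers_table(path):
    from .alignment import TaskSegment

    df = pd.read_csv(path, float_precision="round_trip")
    return [
        TaskSegment(
            task_index=int(r.task_index),
            t_start=float(r.t_start_ms),
            t_end=float(r.t_end_ms),
            completed=bool(r.completed),
        )
        for r in df.itertuples()
    ]
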