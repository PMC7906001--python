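"""Per-task coordination metrics and group-level summaries.

Six metrics describe one participant-task:

========  ============================================================
FD (ms)   mean fixation duration of the eye signal within the task
FN        number of eye fixations (stable events)
SN        number of saccades (eye rapid events)
SSD (ms)  mean hand stand-still duration
SSN       number of hand stand-stills (stable events)
SSM       number of sudden sharp hand movements (rapid events)
========  ============================================================

Events are clipped to the half-open task window; an event straddling a
boundary contributes its clipped duration and is counted once, in the
segment containing its midpoint.  FD/SSD are missing (NaN), not zero, when
the corresponding count is zero, and missing values are excluded from all
means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import TaskSegment
from .errors import CoverageError
from .events import RAPID, STABLE, EventSequence

__all__ = [
    "MetricsRecord",
    "eye_metrics",
    "hand_metrics",
    "task_metrics",
    "summarize",
]


@dataclass
class MetricsRecord:
    """The six metrics for one participant / scenario / task."""

    participant: str
    scenario: str
    task: int
    FD: float
    FN: int
    SN: int
    SSD: float
    SSN: int
    SSM: int

    def as_row(self) -> dict:
        return {
            "participant": self.participant,
            "scenario": self.scenario,
            "task": self.task,
            "FD_ms": self.FD,
            "FN": self.FN,
            "SN": self.SN,
            "SSD_ms": self.SSD,
            "SSN": self.SSN,
            "SSM": self.SSM,
        }


def _clipped_events(events: EventSequence, segment: TaskSegment):
    """Events whose midpoint falls in the segment, with clipped durations."""
    w0, w1 = events.window
    if segment.t_start < w0 - 1e-6 or segment.t_end > w1 + 1e-6:
        raise CoverageError(
            f"events cover [{w0:.1f}, {w1:.1f}) but segment is "
            f"[{segment.t_start:.1f}, {segment.t_end:.1f})"
        )
    stable_durs, n_rapid = [], 0
    for ev in events.events:
        if not segment.t_start <= ev.midpoint < segment.t_end:
            continue
        if ev.kind == STABLE:
            clipped = min(ev.t_end, segment.t_end) - max(ev.t_start, segment.t_start)
            stable_durs.append(clipped)
        elif ev.kind == RAPID:
            n_rapid += 1
    return stable_durs, n_rapid


def eye_metrics(events: EventSequence, segment: TaskSegment) -> tuple[float, int, int]:
    """(FD, FN, SN) for one task window; FD is NaN when FN = 0."""
    stable_durs, n_rapid = _clipped_events(events, segment)
    fn = len(stable_durs)
    fd = float(np.mean(stable_durs)) if fn else math.nan
    return fd, fn, n_rapid


def hand_metrics(events: EventSequence, segment: TaskSegment) -> tuple[float, int, int]:
    """(SSD, SSN, SSM) for one task window; identical contract to
    :func:`eye_metrics` with stand-stills as stable events."""
    return eye_metrics(events, segment)


def task_metrics(
    eye_events: EventSequence,
    hand_events: EventSequence,
    segment: TaskSegment,
    participant: str = "p0",
    scenario: str = "s1",
) -> MetricsRecord:
    fd, fn, sn = eye_metrics(eye_events, segment)
    ssd, ssn, ssm = hand_metrics(hand_events, segment)
    return MetricsRecord(
        participant=participant, scenario=scenario, task=segment.task_index,
        FD=fd, FN=fn, SN=sn, SSD=ssd, SSN=ssn, SSM=ssm,
    )


METRIC_NAMES = ["FD_ms", "FN", "SN", "SSD_ms", "SSN", "SSM"]


def participant_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant means across tasks (missing values excluded)."""
    return records.groupby(["participant", "scenario"], as_index=False)[METRIC_NAMES].mean()


def summarize(records: pd.DataFrame, groups: dict[str, str]) -> pd.DataFrame:
    """Group-level descriptive table: mean and SD across participants.

    ``records`` is a per-task metrics table (columns as written by
    :func:`gazehand.streams.write_metrics_table`); ``groups`` maps
    participant id to group label.  Each participant is first reduced to the
    mean of their task values, then M and sample SD (ddof=1) are taken over
    participants.  A single-participant group reports SD = 0 and is flagged
    through ``n``.
    """
    per_part = participant_means(records)
    per_part["group"] = per_part["participant"].map(groups)
    if per_part["group"].isna().any():
        missing = per_part.loc[per_part["group"].isna(), "participant"].tolist()
        raise ValueError(f"no group label for participants {missing}")
    rows = []
    for group, sub in per_part.groupby("group"):
        if len(sub) == 0:
            raise ValueError(f"group {group!r} has no participants")
        for metric in METRIC_NAMES:
            vals = sub[metric].dropna().to_numpy()
            n = vals.size
            rows.append(
                {
                    "group": group,
                    "metric": metric,
                    "M": float(vals.mean()) if n else math.nan,
                    "SD": float(vals.std(ddof=1)) if n > 1 else 0.0,
                    "n": int(n),
                }
            )
    return pd.DataFrame(rows, columns=["group", "metric", "M", "SD", "n"])
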