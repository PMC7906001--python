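"""Temporal alignment of gaze and hand streams and task segmentation.

The two acquisition devices run on independent clocks.  Alignment applies a
signed millisecond offset to the hand clock and intersects the covered time
ranges; streams are never resampled because event classification is
sampling-rate independent.  Sessions are assumed drift-free over the
couple-of-minutes recordings considered here.

Task segmentation cuts the common window into at most ten half-open
``[t_start, t_end)`` segments of at most 10 s each, either from an explicit
marker table or from a fixed consecutive grid.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import AlignmentError, SegmentationError
from .streams import GazeStream, HandStream

__all__ = ["Session", "TaskSegment", "align_session", "segment_tasks"]

MAX_TASKS = 10
MAX_TASK_MS = 10_000.0


@dataclass
class TaskSegment:
    """One repetitive task window, half-open ``[t_start, t_end)`` in ms."""

    task_index: int
    t_start: float
    t_end: float
    completed: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.task_index < MAX_TASKS:
            raise SegmentationError(f"task_index must be in 0..{MAX_TASKS - 1}")
        if self.t_end <= self.t_start:
            raise SegmentationError("segment must have positive duration")
        if self.duration > MAX_TASK_MS + 1e-9:
            raise SegmentationError(
                f"task {self.task_index} lasts {self.duration:.1f} ms "
                f"(> {MAX_TASK_MS:.0f} ms limit)"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class Session:
    """An aligned gaze + hand recording with its common time window."""

    gaze: GazeStream
    hand: HandStream
    offset_ms: float
    overlap: tuple[float, float]  # half-open [t0, t1)


def align_session(
    gaze: GazeStream, hand: HandStream, offset_ms: float | str = 0.0
) -> Session:
    """Put both streams on the gaze clock.

    ``offset_ms`` is added to the hand timestamps.  ``"auto"`` aligns stream
    starts (offset = first gaze timestamp - first hand timestamp), the
    simplest contract for simultaneous acquisition.
    """
    if len(gaze) == 0 or len(hand) == 0:
        raise AlignmentError("both streams must be non-empty")
    if offset_ms == "auto":
        offset_ms = float(gaze.t[0] - hand.t[0])
    offset_ms = float(offset_ms)
    hand = hand.shifted(offset_ms)
    t0 = max(float(gaze.t[0]), float(hand.t[0]))
    t1 = min(float(gaze.t[-1]), float(hand.t[-1]))
    if t1 <= t0:
        raise AlignmentError(
            f"streams do not overlap: gaze covers [{gaze.t[0]:.1f}, {gaze.t[-1]:.1f}), "
            f"shifted hand covers [{hand.t[0]:.1f}, {hand.t[-1]:.1f})"
        )
    return Session(gaze=gaze, hand=hand, offset_ms=offset_ms, overlap=(t0, t1))


def segment_tasks(
    session: Session,
    markers: list[TaskSegment] | None = None,
    grid_ms: float = MAX_TASK_MS,
) -> list[TaskSegment]:
    """Cut the session overlap into ordered, non-overlapping task segments.

    With explicit ``markers`` the segments are validated against the
    overlap; without, a fixed grid of consecutive ``grid_ms`` windows
    (clipped to the overlap, at most ten) is generated.
    """
    t0, t1 = session.overlap
    if markers is not None:
        segs = sorted(markers, key=lambda s: s.t_start)
        prev_end = None
        for s in segs:
            if s.t_start < t0 - 1e-9 or s.t_end > t1 + 1e-9:
                raise SegmentationError(
                    f"task {s.task_index} [{s.t_start:.1f}, {s.t_end:.1f}) outside "
                    f"session overlap [{t0:.1f}, {t1:.1f})"
                )
            if prev_end is not None and s.t_start < prev_end - 1e-9:
                raise SegmentationError(f"task {s.task_index} overlaps previous segment")
            prev_end = s.t_end
        if len(segs) > MAX_TASKS:
            raise SegmentationError(f"at most {MAX_TASKS} task segments allowed")
        return segs
    if grid_ms <= 0 or grid_ms > MAX_TASK_MS:
        raise SegmentationError(f"grid_ms must be in (0, {MAX_TASK_MS:.0f}]")
    segs = []
    start = t0
    for k in range(MAX_TASKS):
        if start >= t1:
            break
        end = min(start + grid_ms, t1)
        segs.append(TaskSegment(task_index=k, t_start=start, t_end=end))
        start = end
    return segs
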