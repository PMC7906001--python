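"""Adaptive velocity-threshold event classification.

A fully automatic, velocity-based classifier that labels any d-dimensional
kinematic stream into *stable* intervals (fixations for gaze, stand-stills
for the hand), *rapid* intervals (saccades, sudden sharp movements) and
*gaps* (blinks, track loss).  The speed threshold separating stable from
rapid motion is estimated from the data of each signal individually, so the
same algorithm applies unchanged to gaze in pixels and hand trajectories in
device units, at any sampling rate.

Threshold scheme
----------------
Starting from ``theta_0 = mean + k*sd`` over all speeds, the mean and
standard deviation are recomputed over sub-threshold speeds only and the
threshold re-set to ``mean + k*sd`` until the update falls below a
tolerance.  On noise-only input this converges to a fixed point of the
truncated-moment map; on bimodal input (slow noise + fast events) it
settles between the modes because the fast mode is progressively excluded.
The threshold is data-driven, which makes the labeling invariant under
uniform spatial rescaling of the input.

Interval construction
---------------------
Each inter-sample interval ``[t_i, t_{i+1})`` receives a label: *gap* if
either bounding sample is invalid or non-finite, otherwise *stable*/*rapid*
by comparing the interval speed to the threshold.  Runs of equal labels are
then refined:

1. stable runs shorter than ``min_stable_ms`` are relabeled rapid;
2. adjacent same-kind runs are coalesced;
3. rapid runs shorter than ``min_rapid_ms`` whose two neighbours are both
   stable are relabeled stable;
4. adjacent same-kind runs are coalesced again.

Gaps never change kind and never merge with non-gap runs, so a stable run
split by a gap counts as two events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, InsufficientDataError
from .streams import GazeStream, HandStream

__all__ = [
    "STABLE",
    "RAPID",
    "GAP",
    "ClassifierConfig",
    "VelocitySeries",
    "ThresholdEstimate",
    "EventInterval",
    "EventSequence",
    "compute_velocity",
    "estimate_threshold",
    "refine_runs",
    "classify_events",
    "classify_trajectory",
]

STABLE = "stable"
RAPID = "rapid"
GAP = "gap"


@dataclass(frozen=True)
class ClassifierConfig:
    """Tunable knobs of the classifier; the defaults require no per-dataset
    adjustment because the threshold itself is data-driven.

    ``k`` is the number of noise standard deviations above the noise mean at
    which motion counts as rapid; ``floor`` is a lower bound on the
    threshold in units/s guarding degenerate (constant) input.
    """

    k: float = 3.0
    tolerance: float = 1.0          # units/s, threshold-iteration stop
    max_iter: int = 50
    floor: float = 1e-6             # units/s
    min_stable_ms: float = 50.0
    min_rapid_ms: float = 10.0
    binocular_rule: str = "conjunction"  # or "disjunction"
    median_filter: bool = False     # optional 3-sample median on speeds
    channel: str = "tool"           # hand channel to classify


@dataclass
class VelocitySeries:
    """Finite-difference speeds at inter-sample midpoints, in units/s."""

    t: np.ndarray              # (n-1,) midpoint times, ms
    speed: np.ndarray          # (n-1,) magnitudes, units/s
    per_channel: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class ThresholdEstimate:
    """Converged data-driven speed threshold for one signal."""

    theta: float
    noise_mu: float
    noise_sigma: float
    n_iter: int
    converged: bool


@dataclass
class EventInterval:
    """One classified interval, half-open ``[t_start, t_end)`` in ms.

    ``centroid`` is the d-dimensional mean position of the member samples
    (``None`` for gaps).
    """

    kind: str
    t_start: float
    t_end: float
    centroid: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.t_start + self.t_end)


@dataclass
class EventSequence:
    """Ordered, non-overlapping intervals jointly covering one classified
    window of one signal."""

    signal_id: str
    events: list[EventInterval]
    theta_used: ThresholdEstimate | dict[str, ThresholdEstimate] | None
    window: tuple[float, float]
    ndim: int = 2

    def of_kind(self, kind: str) -> list[EventInterval]:
        return [e for e in self.events if e.kind == kind]


def compute_velocity(t, positions) -> VelocitySeries:
    """Finite-difference speed series of a d-dimensional trajectory.

    ``speed[i] = ||x[i+1] - x[i]|| / (t[i+1] - t[i])`` scaled to units per
    second.  Non-finite positions propagate to NaN speeds (gap handling is
    the caller's job).
    """
    t = np.asarray(t, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        positions = positions[:, None]
    if t.shape[0] < 2:
        raise InsufficientDataError("need at least 2 samples to compute velocity")
    dt = np.diff(t)
    dup = np.nonzero(dt == 0)[0]
    if dup.size:
        raise FormatError("duplicate timestamps", row=int(dup[0]) + 2)
    disp = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    speed = disp / dt * 1000.0
    return VelocitySeries(t=0.5 * (t[:-1] + t[1:]), speed=speed)


def _median3(x: np.ndarray) -> np.ndarray:
    if x.shape[0] < 3:
        return x
    out = x.copy()
    stacked = np.stack([x[:-2], x[1:-1], x[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def estimate_threshold(vel, config: ClassifierConfig = ClassifierConfig()) -> ThresholdEstimate:
    """Iterate ``theta <- mean + k*sd`` over sub-threshold speeds.

    Accepts a :class:`VelocitySeries` or a plain speed array; NaN speeds are
    ignored.  Requires at least 10 finite speed samples.  Degenerate input
    (all speeds identical) yields the floor threshold, flagged converged.
    """
    speeds = vel.speed if isinstance(vel, VelocitySeries) else np.asarray(vel, dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if speeds.size < 10:
        raise InsufficientDataError(
            f"threshold estimation needs >= 10 speed samples, got {speeds.size}"
        )
    if np.ptp(speeds) == 0.0:
        mu = float(speeds[0])
        return ThresholdEstimate(
            theta=max(mu, config.floor), noise_mu=mu, noise_sigma=0.0,
            n_iter=0, converged=True,
        )
    theta = float(speeds.mean() + config.k * speeds.std())
    mu, sigma = float(speeds.mean()), float(speeds.std())
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        sub = speeds[speeds < theta]
        if sub.size < 2:
            # threshold fell below (almost) all data: clamp to floor
            theta_new = config.floor
            mu, sigma = (float(sub.mean()), 0.0) if sub.size else (0.0, 0.0)
        else:
            mu, sigma = float(sub.mean()), float(sub.std())
            theta_new = max(mu + config.k * sigma, config.floor)
        done = abs(theta_new - theta) < config.tolerance
        theta = theta_new
        if done:
            converged = True
            break
    return ThresholdEstimate(
        theta=float(theta), noise_mu=mu, noise_sigma=sigma,
        n_iter=n_iter, converged=converged,
    )


def _group_runs(labels: list[str]) -> list[tuple[str, int, int]]:
    """Run-length encode labels into (kind, start, stop) half-open index runs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((labels[start], start, i))
            start = i
    return runs


def refine_runs(
    labels,
    durations,
    min_stable_ms: float,
    min_rapid_ms: float,
) -> list[tuple[str, int, int]]:
    """Apply the run-refinement rules to per-interval labels.

    ``durations[i]`` is the length in ms of interval ``i``.  Returns the
    final (kind, start, stop) runs over interval indices.  This function is
    the single source of truth for the grouping/filtering semantics; the
    classifier and the synthetic-data recovery tests both go through it.
    """
    labels = list(labels)
    durations = np.asarray(durations, dtype=float)
    runs = _group_runs(labels)

    def run_dur(r):
        return float(durations[r[1]:r[2]].sum())

    # rule 1: short stable runs become rapid (evaluated on the initial runs)
    runs = [
        (RAPID, a, b) if (k == STABLE and run_dur((k, a, b)) < min_stable_ms) else (k, a, b)
        for k, a, b in runs
    ]

    def coalesce(rs):
        out = []
        for r in rs:
            if out and out[-1][0] == r[0]:
                out[-1] = (r[0], out[-1][1], r[2])
            else:
                out.append(r)
        return out

    runs = coalesce(runs)

    # rule 3: short rapid runs flanked by stable on both sides become stable
    new = []
    for i, r in enumerate(runs):
        k, a, b = r
        if (
            k == RAPID
            and run_dur(r) < min_rapid_ms
            and 0 < i < len(runs) - 1
            and runs[i - 1][0] == STABLE
            and runs[i + 1][0] == STABLE
        ):
            new.append((STABLE, a, b))
        else:
            new.append(r)
    return coalesce(new)


def _intervals_from_runs(
    runs, t: np.ndarray, positions: np.ndarray
) -> list[EventInterval]:
    """Turn interval-index runs into timed events with sample centroids.

    A run over intervals ``a..b-1`` spans samples ``a..b`` and the time
    window ``[t[a], t[b])``.
    """
    events = []
    for kind, a, b in runs:
        if kind == GAP:
            centroid = None
        else:
            pts = positions[a:b + 1]
            finite = np.isfinite(pts).all(axis=1)
            centroid = pts[finite].mean(axis=0) if finite.any() else None
        events.append(
            EventInterval(kind=kind, t_start=float(t[a]), t_end=float(t[b]), centroid=centroid)
        )
    return events


def classify_trajectory(
    t,
    positions,
    valid=None,
    config: ClassifierConfig = ClassifierConfig(),
    signal_id: str = "trajectory",
) -> EventSequence:
    """Classify a single d-dimensional trajectory into stable/rapid/gap
    events covering ``[t[0], t[-1])`` exactly."""
    t = np.asarray(t, dtype=float)
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 1:
        positions = positions[:, None]
    if len(t) < 2:
        raise InsufficientDataError("need at least 2 samples to classify")
    finite = np.isfinite(positions).all(axis=1)
    valid = finite if valid is None else (np.asarray(valid, dtype=bool) & finite)
    vel = compute_velocity(t, positions)
    speed = _median3(vel.speed) if config.median_filter else vel.speed
    pair_valid = valid[:-1] & valid[1:]
    est = estimate_threshold(speed[pair_valid & np.isfinite(speed)], config)
    labels = [
        GAP if not pair_valid[i] else (STABLE if speed[i] < est.theta else RAPID)
        for i in range(speed.shape[0])
    ]
    runs = refine_runs(labels, np.diff(t), config.min_stable_ms, config.min_rapid_ms)
    events = _intervals_from_runs(runs, t, positions)
    return EventSequence(
        signal_id=signal_id,
        events=events,
        theta_used=est,
        window=(float(t[0]), float(t[-1])),
        ndim=positions.shape[1],
    )


def _classify_gaze(stream: GazeStream, config: ClassifierConfig) -> EventSequence:
    t = stream.t
    if len(t) < 2:
        raise InsufficientDataError("need at least 2 samples to classify")
    vel_l = compute_velocity(t, stream.left)
    vel_r = compute_velocity(t, stream.right)
    sp_l = _median3(vel_l.speed) if config.median_filter else vel_l.speed
    sp_r = _median3(vel_r.speed) if config.median_filter else vel_r.speed
    valid = stream.valid
    pair_valid = valid[:-1] & valid[1:]
    ok = pair_valid & np.isfinite(sp_l) & np.isfinite(sp_r)
    est_l = estimate_threshold(sp_l[ok], config)
    est_r = estimate_threshold(sp_r[ok], config)
    sub_l = sp_l < est_l.theta
    sub_r = sp_r < est_r.theta
    if config.binocular_rule == "conjunction":
        sub = sub_l & sub_r
    elif config.binocular_rule == "disjunction":
        sub = sub_l | sub_r
    else:
        raise ValueError(f"unknown binocular_rule {config.binocular_rule!r}")
    labels = [
        GAP if not pair_valid[i] else (STABLE if sub[i] else RAPID)
        for i in range(sub.shape[0])
    ]
    runs = refine_runs(labels, np.diff(t), config.min_stable_ms, config.min_rapid_ms)
    events = _intervals_from_runs(runs, t, stream.cyclopean)
    return EventSequence(
        signal_id="eye",
        events=events,
        theta_used={"left": est_l, "right": est_r},
        window=(float(t[0]), float(t[-1])),
        ndim=2,
    )


def classify_events(stream, config: ClassifierConfig = ClassifierConfig()) -> EventSequence:
    """Classify a :class:`GazeStream` (binocular, per-eye thresholds) or a
    :class:`HandStream` (``config.channel`` selects tool or camera).

    For gaze, an interval is stable only when *both* eyes are sub-threshold
    under the default conjunction rule; either-eye invalidity makes it a
    gap.
    """
    if isinstance(stream, GazeStream):
        return _classify_gaze(stream, config)
    if isinstance(stream, HandStream):
        channel = config.channel
        return classify_trajectory(
            stream.t,
            stream.positions(channel),
            valid=stream.valid_mask(channel),
            config=config,
            signal_id=channel if channel != "camera" else "cam",
        )
    raise TypeError(f"cannot classify object of type {type(stream).__name__}")
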