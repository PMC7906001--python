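"""Synthetic gaze + hand cohort generator with planted ground truth.

The generator emulates the study design this package analyses: two skill
groups, ten repetitive tasks of at most 10 s per scenario, binocular gaze
sampled at a nominal 60 Hz on a 1920x1080 top-left pixel frame, and a 3-D
haptic tool trajectory at a nominal 100 Hz.  Every stage of the analysis
pipeline can therefore be tested against exact ground truth without any
recorded data.

Planting mechanism
------------------
Eye-hand coupling is planted at the per-task metric level through a
Gaussian copula: for each task a six-dimensional latent normal vector with
correlation matrix Sigma (unit diagonal; the three eye-hand pair couplings
FD-SSD, FN-SSN, SN-SSM as off-diagonal entries) is drawn and mapped through
fixed monotone transforms to the six metric values.  A task plan then lays
out events realising those values exactly, and the renderer turns the plan
into sample streams.

Because classified event sequences alternate between stable and rapid
intervals, the rapid-event count inside a gap-free window is tied to the
stable-event count (+/-1).  The generator therefore uses short signal-loss
windows -- blinks in the gaze stream, tracker dropouts in the hand stream --
to decouple the counts: a gap between two rapid intervals splits them into
separate events, and a gap between two stable intervals separates
fixations/stand-stills without an intervening rapid event.  This is also
what makes the independently drawn FN/SN (and SSN/SSM) targets realisable.

Sensor noise during stable events is modelled as band-limited oscillatory
jitter (two incommensurate drift/tremor frequencies with random phases)
rather than white noise.  Band-limited jitter has a bounded sample-to-sample
velocity, so the adaptive threshold cleanly separates it from planted rapid
movements at any sampling rate -- which is exactly the rate-independence
contract the classifier is supposed to honour.  White measurement noise, by
contrast, would have a sampling-rate dependent velocity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import TaskSegment
from .errors import GazehandError
from .events import GAP, RAPID, STABLE, EventInterval, EventSequence
from .metrics import MetricsRecord
from .streams import (
    GazeStream,
    HandStream,
    write_event_table,
    write_gaze_table,
    write_hand_table,
    write_markers_table,
    write_metrics_table,
)

__all__ = [
    "GroupProfile",
    "CohortSpec",
    "TaskPlan",
    "INTERMEDIATE",
    "NOVICE_SCENARIO1",
    "NOVICE_SCENARIO2",
    "coupling_matrix",
    "plan_tasks",
    "render_gaze_stream",
    "render_hand_stream",
    "simulate_participant",
    "simulate_cohort",
    "write_cohort",
    "SimulatedCohort",
    "ParticipantData",
]

# fixed event-geometry constants (ms / px / device-units).  Rapid events
# have a fixed spatial amplitude so their speed mode is narrow; the adaptive
# mean + k*sd threshold separates a narrow fast mode from the noise mode
# reliably as long as rapid intervals stay a small minority (< ~10%) of the
# classified samples, which the metric transforms below guarantee.
EYE_SACCADE_MS = 50.0
HAND_TRANSPORT_MS = 60.0
GAP_MS = 120.0                 # within-task blink / dropout
EYE_JUMP_PX = 150.0            # saccade amplitude -> 3000 px/s
HAND_JUMP = 40.0               # transport amplitude -> ~667 units/s mean
EYE_BOX = ((60.0, 1860.0), (60.0, 1020.0))
HAND_BOX = ((10.0, 190.0),) * 3
VERGENCE_PX = 8.0              # horizontal left/right eye separation
EYE_JITTER_HZ = (4.1, 9.7)     # fixational drift + tremor bands
HAND_JITTER_HZ = (2.9, 6.1)
TIMING_JITTER_MS = 0.3

@dataclass(frozen=True)
class GroupProfile:
    """Planted eye-hand couplings for one skill group.

    The default profiles mirror the qualitative pattern reported for
    intermediate vs novice surgeons: strong negative fixation couplings and
    a strong positive saccade coupling for intermediates; weaker couplings
    with scenario-dependent signs for novices.
    """

    rho_fd_ssd: float
    rho_fn_ssn: float
    rho_sn_ssm: float


INTERMEDIATE = GroupProfile(-0.8, -0.8, +0.8)
NOVICE_SCENARIO1 = GroupProfile(+0.45, +0.45, +0.55)
NOVICE_SCENARIO2 = GroupProfile(-0.45, -0.45, +0.10)


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a simulated cohort."""

    n_intermediate: int = 5
    n_novice: int = 10
    tasks_per_scenario: int = 10
    task_ms: float = 10_000.0
    eye_rate_hz: float = 60.0
    hand_rate_hz: float = 100.0
    gaze_noise_px: float = 0.5      # RMS fixational jitter amplitude
    hand_noise: float = 0.3         # RMS stand-still jitter, device units
    intertask_gap_ms: float = 300.0
    scenario: str = "s1"
    profiles: dict = field(
        default_factory=lambda: {
            "intermediate": INTERMEDIATE,
            "novice": NOVICE_SCENARIO1,
        }
    )


@dataclass
class PlanEvent:
    """One planned interval: kind, duration and start/end positions."""

    kind: str
    duration: float
    p0: np.ndarray | None = None
    p1: np.ndarray | None = None


@dataclass
class TaskPlan:
    """Event layout of one task, with the metric values it implies."""

    duration_ms: float
    eye_events: list[PlanEvent]
    hand_events: list[PlanEvent]
    planted: dict[str, float]


def coupling_matrix(profile: GroupProfile) -> np.ndarray:
    """6x6 latent correlation matrix over (FD, FN, SN, SSD, SSN, SSM)."""
    sigma = np.eye(6)
    for (i, j), rho in zip(
        [(0, 3), (1, 4), (2, 5)],
        [profile.rho_fd_ssd, profile.rho_fn_ssn, profile.rho_sn_ssm],
    ):
        sigma[i, j] = sigma[j, i] = rho
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] < -1e-10:
        raise GazehandError(
            f"coupling matrix not positive semi-definite (eigenvalue {eig[0]:.4g})"
        )
    return sigma


def _latent_sqrt(sigma: np.ndarray) -> np.ndarray:
    # eigh-based square root so |rho| = 1 profiles also work
    w, v = np.linalg.eigh(sigma)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def _metrics_from_latent(z: np.ndarray) -> dict[str, float]:
    """Monotone maps from latent normals to metric targets.

    Durations use shifted-lognormal maps so fixations and stand-stills stay
    well above the classifier's minimum-duration rule; counts round a
    linear map.  Monotonicity preserves the copula's rank correlation.  The
    levels keep rapid movement a small minority of each signal's time
    (fixations of a few hundred ms, a handful of saccades per task), the
    regime in which a data-driven velocity threshold is well defined.
    """
    z = np.clip(z, -3.0, 3.0)
    return {
        "FD": 330.0 + 150.0 * float(np.exp(0.45 * z[0])),
        "FN": int(np.clip(np.round(10.0 + 1.8 * z[1]), 4, 16)),
        "SN": int(np.clip(np.round(6.0 + 1.8 * z[2]), 0, 12)),
        "SSD": 400.0 + 160.0 * float(np.exp(0.4 * z[3])),
        "SSN": int(np.clip(np.round(8.0 + 1.5 * z[4]), 3, 13)),
        "SSM": int(np.clip(np.round(5.0 + 1.6 * z[5]), 0, 10)),
    }


def _uniform_point(rng: np.random.Generator, box) -> np.ndarray:
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    return rng.uniform(lo, hi)


def _step_point(rng: np.random.Generator, box, current: np.ndarray, dist: float) -> np.ndarray:
    """A point exactly ``dist`` away from ``current``, inside the box.

    The fixed step keeps every rapid movement at the same spatial amplitude
    (and hence a narrow speed mode).  A valid direction always exists
    because the box is much larger than the step.
    """
    lo = np.array([b[0] for b in box])
    hi = np.array([b[1] for b in box])
    for _ in range(500):
        d = rng.standard_normal(current.shape[0])
        d /= np.linalg.norm(d)
        p = current + dist * d
        if np.all(p >= lo) and np.all(p <= hi):
            return p
    return np.clip(p, lo, hi)


def _layout_stream(
    n_stable: int,
    stable_ms: float,
    n_rapid: int,
    rapid_ms: float,
    rng: np.random.Generator,
    box,
    jump: float,
) -> list[PlanEvent]:
    """Lay out stable events separated by slots of rapid/gap intervals.

    ``n_stable - 1`` separator slots are filled so that the stream contains
    exactly ``n_rapid`` rapid intervals: surplus rapids are split within a
    slot by gaps, missing ones are replaced by gap-only separators (blinks /
    dropouts with no intervening movement event).
    """
    slots = max(n_stable - 1, 0)
    if slots == 0:
        slot_rapids = []
    elif n_rapid >= slots:
        slot_rapids = np.ones(slots, dtype=int)
        extra = n_rapid - slots
        order = rng.permutation(slots)
        for i in range(extra):
            slot_rapids[order[i % slots]] += 1
    else:
        slot_rapids = np.zeros(slots, dtype=int)
        slot_rapids[rng.choice(slots, size=n_rapid, replace=False)] = 1

    events: list[PlanEvent] = []
    cur = _uniform_point(rng, box)

    def add_rapid():
        nonlocal cur
        nxt = _step_point(rng, box, cur, jump)
        events.append(PlanEvent(RAPID, rapid_ms, cur.copy(), nxt))
        cur = nxt

    def add_gap():
        nonlocal cur
        events.append(PlanEvent(GAP, GAP_MS))
        cur = _uniform_point(rng, box)  # signal reappears elsewhere

    def add_stable():
        events.append(PlanEvent(STABLE, stable_ms, cur.copy(), cur.copy()))

    if n_stable == 0:
        for r in range(n_rapid):
            if r:
                add_gap()
            add_rapid()
        return events

    add_stable()
    for k in slot_rapids:
        if k == 0:
            add_gap()
        else:
            for r in range(int(k)):
                if r:
                    add_gap()
                add_rapid()
        add_stable()
    # rapids that cannot be placed between stables (n_stable <= 1)
    placed = int(np.sum(slot_rapids)) if slots else 0
    for r in range(n_rapid - placed):
        add_gap() if r else None
        add_rapid()
    return events


def _stream_duration(events: list[PlanEvent]) -> float:
    return float(sum(e.duration for e in events))


def _rescale_stable(events: list[PlanEvent], factor: float) -> None:
    for e in events:
        if e.kind == STABLE:
            e.duration *= factor


def plan_tasks(
    spec: CohortSpec,
    profile: GroupProfile,
    rng: np.random.Generator,
    n_tasks: int | None = None,
) -> list[TaskPlan]:
    """Draw per-task latent metric vectors and lay out matching event plans.

    The planted metric values recorded on each plan are exactly those
    implied by the final layout (a rare over-budget plan rescales stable
    durations to fit ``task_ms`` and records the rescaled value).
    """
    n_tasks = spec.tasks_per_scenario if n_tasks is None else n_tasks
    sigma = coupling_matrix(profile)
    root = _latent_sqrt(sigma)
    plans = []
    for _ in range(n_tasks):
        z = root @ rng.standard_normal(6)
        m = _metrics_from_latent(z)
        eye = _layout_stream(
            m["FN"], m["FD"], m["SN"], EYE_SACCADE_MS, rng, EYE_BOX, EYE_JUMP_PX
        )
        hand = _layout_stream(
            m["SSN"], m["SSD"], m["SSM"], HAND_TRANSPORT_MS, rng, HAND_BOX, HAND_JUMP
        )
        for ev_list, count_key, dur_key in ((eye, "FN", "FD"), (hand, "SSN", "SSD")):
            d = _stream_duration(ev_list)
            if d > spec.task_ms:
                stable_total = sum(e.duration for e in ev_list if e.kind == STABLE)
                other = d - stable_total
                factor = (spec.task_ms - other) / stable_total
                if factor <= 0:
                    raise GazehandError("task plan cannot fit the task window")
                _rescale_stable(ev_list, factor)
                m[dur_key] *= factor
        d_eye, d_hand = _stream_duration(eye), _stream_duration(hand)
        d = max(d_eye, d_hand)
        if d - d_eye > 1e-9:
            eye.append(PlanEvent(GAP, d - d_eye))
        if d - d_hand > 1e-9:
            hand.append(PlanEvent(GAP, d - d_hand))
        plans.append(TaskPlan(duration_ms=d, eye_events=eye, hand_events=hand, planted=m))
    return plans


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _absolute_events(events: list[PlanEvent], t0: float):
    out = []
    t = t0
    for e in events:
        out.append((e.kind, t, t + e.duration, e.p0, e.p1))
        t += e.duration
    return out, t


def _oscillation(t_ms: np.ndarray, amp: float, freqs, phases: np.ndarray) -> np.ndarray:
    """Band-limited jitter: sum of two unit-RMS sinusoids per axis."""
    t_s = t_ms / 1000.0
    out = np.zeros((t_ms.shape[0], phases.shape[0]))
    for j, f in enumerate(freqs):
        out += amp * np.sin(2 * np.pi * f * t_s[:, None] + phases[None, :, j])
    return out


def _sample_times(t0: float, t1: float, rate_hz: float, rng: np.random.Generator) -> np.ndarray:
    period = 1000.0 / rate_hz
    n = int(np.floor((t1 - t0) / period))
    base = t0 + np.arange(n) * period
    jitter = rng.uniform(0.0, 2 * TIMING_JITTER_MS, size=n)
    jitter[0] = 0.0  # anchor the stream head so the window covers t0 exactly
    return base + jitter


def _render_channel(
    abs_events,
    t: np.ndarray,
    rng: np.random.Generator,
    amp: float,
    freqs,
    ndim: int,
    smooth_rapid: bool,
    pos_offset: np.ndarray | None = None,
):
    """Positions + validity for one channel on a given sample grid."""
    phases = rng.uniform(0, 2 * np.pi, size=(ndim, len(freqs)))
    pos = np.full((t.shape[0], ndim), np.nan)
    valid = np.ones(t.shape[0], dtype=bool)
    starts = np.array([e[1] for e in abs_events])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(abs_events) - 1)
    for i, (kind, e0, e1, p0, p1) in enumerate(abs_events):
        sel = idx == i
        if not sel.any():
            continue
        if kind == GAP:
            valid[sel] = False
            continue
        if kind == STABLE:
            pos[sel] = p0
        else:
            s = (t[sel] - e0) / (e1 - e0)
            ramp = (1 - np.cos(np.pi * s)) / 2 if smooth_rapid else s
            pos[sel] = p0 + ramp[:, None] * (p1 - p0)
        if pos_offset is not None:
            pos[sel] += pos_offset
    jitter = _oscillation(t, amp, freqs, phases)
    pos[valid] += jitter[valid]
    return pos, valid


def _truth_sequence(abs_events, signal_id: str, ndim: int) -> EventSequence:
    events = []
    for kind, e0, e1, p0, p1 in abs_events:
        if kind == GAP or p0 is None:
            cen = None
        else:
            cen = 0.5 * (np.asarray(p0) + np.asarray(p1))
        events.append(EventInterval(kind=kind, t_start=e0, t_end=e1, centroid=cen))
    return EventSequence(
        signal_id=signal_id, events=events, theta_used=None,
        window=(abs_events[0][1], abs_events[-1][2]), ndim=ndim,
    )


def render_gaze_stream(
    plan: TaskPlan,
    rate_hz: float = 60.0,
    rng: np.random.Generator | None = None,
    noise_px: float = 0.5,
    t0: float = 0.0,
) -> tuple[GazeStream, EventSequence]:
    """Render one task plan as a binocular gaze stream plus ground truth.

    Fixations are jittered around their centroid (the two eyes carry a
    small fixed vergence disparity and independent jitter phases), saccades
    are constant-velocity straight lines, blinks are invalid samples with
    sentinel coordinates.
    """
    rng = np.random.default_rng() if rng is None else rng
    period = 1000.0 / rate_hz
    shortest = min(
        (e.duration for e in plan.eye_events if e.kind != GAP), default=np.inf
    )
    if shortest < 2 * period:
        raise GazehandError(
            f"sampling rate {rate_hz} Hz too low for shortest planned event "
            f"({shortest:.0f} ms)"
        )
    abs_events, _ = _absolute_events(plan.eye_events, t0)
    t = _sample_times(t0, t0 + plan.duration_ms, rate_hz, rng)
    off = np.array([VERGENCE_PX / 2, 0.0])
    left, valid_l = _render_channel(
        abs_events, t, rng, noise_px, EYE_JITTER_HZ, 2, smooth_rapid=False, pos_offset=-off
    )
    right, valid_r = _render_channel(
        abs_events, t, rng, noise_px, EYE_JITTER_HZ, 2, smooth_rapid=False, pos_offset=off
    )
    left[~valid_l] = -1.0
    right[~valid_r] = -1.0
    stream = GazeStream(
        t=t, left=left, right=right,
        valid_left=valid_l, valid_right=valid_r, nominal_rate_hz=rate_hz,
    )
    return stream, _truth_sequence(abs_events, "eye", 2)


def render_hand_stream(
    plan: TaskPlan,
    rate_hz: float = 100.0,
    rng: np.random.Generator | None = None,
    noise: float = 0.3,
    t0: float = 0.0,
) -> tuple[HandStream, EventSequence]:
    """Render one task plan as a hand stream plus ground truth.

    Stand-stills are low-amplitude 3-D jitter, transports / sharp movements
    are cosine-ramp point-to-point moves, dropouts are NaN samples.  The
    camera channel is rendered as a slow echo of the tool (it is not
    classified by default).
    """
    rng = np.random.default_rng() if rng is None else rng
    period = 1000.0 / rate_hz
    shortest = min(
        (e.duration for e in plan.hand_events if e.kind != GAP), default=np.inf
    )
    if shortest < 2 * period:
        raise GazehandError(
            f"sampling rate {rate_hz} Hz too low for shortest planned event "
            f"({shortest:.0f} ms)"
        )
    abs_events, _ = _absolute_events(plan.hand_events, t0)
    t = _sample_times(t0, t0 + plan.duration_ms, rate_hz, rng)
    tool, valid = _render_channel(
        abs_events, t, rng, noise, HAND_JITTER_HZ, 3, smooth_rapid=True
    )
    tool[~valid] = np.nan
    cam = 0.5 * tool + 50.0  # passive camera echo; same gaps
    stream = HandStream(t=t, tool=tool, cam=cam, nominal_rate_hz=rate_hz)
    return stream, _truth_sequence(abs_events, "tool", 3)


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------

@dataclass
class ParticipantData:
    participant: str
    group: str
    scenario: str
    gaze: GazeStream
    hand: HandStream
    markers: list[TaskSegment]
    truth_eye: EventSequence
    truth_hand: EventSequence
    planted: list[MetricsRecord]


@dataclass
class SimulatedCohort:
    spec: CohortSpec
    participants: list[ParticipantData]

    @property
    def groups(self) -> dict[str, str]:
        return {p.participant: p.group for p in self.participants}

    def planted_records(self) -> pd.DataFrame:
        rows = [r.as_row() for p in self.participants for r in p.planted]
        return pd.DataFrame(rows)


def simulate_participant(
    spec: CohortSpec,
    profile: GroupProfile,
    rng: np.random.Generator,
    participant: str = "p0",
    group: str = "novice",
) -> ParticipantData:
    """Simulate one participant's full scenario (all tasks, one session).

    Tasks are rendered back to back, separated by short signal-loss windows
    in both streams (scene reset between repetitions), so consecutive tasks
    never share a stable event.
    """
    plans = plan_tasks(spec, profile, rng)
    eye_abs, hand_abs, markers, planted = [], [], [], []
    cursor = 0.0
    for k, plan in enumerate(plans):
        ev_eye, _ = _absolute_events(plan.eye_events, cursor)
        ev_hand, _ = _absolute_events(plan.hand_events, cursor)
        eye_abs.extend(ev_eye)
        hand_abs.extend(ev_hand)
        markers.append(
            TaskSegment(task_index=k, t_start=cursor, t_end=cursor + plan.duration_ms)
        )
        planted.append(
            MetricsRecord(
                participant=participant, scenario=spec.scenario, task=k,
                FD=plan.planted["FD"], FN=plan.planted["FN"], SN=plan.planted["SN"],
                SSD=plan.planted["SSD"], SSN=plan.planted["SSN"], SSM=plan.planted["SSM"],
            )
        )
        cursor += plan.duration_ms
        gap = (GAP, cursor, cursor + spec.intertask_gap_ms, None, None)
        eye_abs.append(gap)
        hand_abs.append(gap)
        cursor += spec.intertask_gap_ms

    t_eye = _sample_times(0.0, cursor, spec.eye_rate_hz, rng)
    off = np.array([VERGENCE_PX / 2, 0.0])
    left, valid_l = _render_channel(
        eye_abs, t_eye, rng, spec.gaze_noise_px, EYE_JITTER_HZ, 2,
        smooth_rapid=False, pos_offset=-off,
    )
    right, valid_r = _render_channel(
        eye_abs, t_eye, rng, spec.gaze_noise_px, EYE_JITTER_HZ, 2,
        smooth_rapid=False, pos_offset=off,
    )
    left[~valid_l] = -1.0
    right[~valid_r] = -1.0
    gaze = GazeStream(
        t=t_eye, left=left, right=right,
        valid_left=valid_l, valid_right=valid_r, nominal_rate_hz=spec.eye_rate_hz,
    )
    t_hand = _sample_times(0.0, cursor, spec.hand_rate_hz, rng)
    tool, valid_h = _render_channel(
        hand_abs, t_hand, rng, spec.hand_noise, HAND_JITTER_HZ, 3, smooth_rapid=True
    )
    tool[~valid_h] = np.nan
    hand = HandStream(
        t=t_hand, tool=tool, cam=0.5 * tool + 50.0, nominal_rate_hz=spec.hand_rate_hz
    )
    return ParticipantData(
        participant=participant, group=group, scenario=spec.scenario,
        gaze=gaze, hand=hand, markers=markers,
        truth_eye=_truth_sequence(eye_abs, "eye", 2),
        truth_hand=_truth_sequence(hand_abs, "tool", 3),
        planted=planted,
    )


def simulate_cohort(spec: CohortSpec, seed: int) -> SimulatedCohort:
    """Simulate a full two-group cohort; bit-reproducible for a given
    spec + seed."""
    ss = np.random.SeedSequence(seed)
    roster = [("intermediate", i) for i in range(spec.n_intermediate)]
    roster += [("novice", i) for i in range(spec.n_novice)]
    children = ss.spawn(len(roster))
    participants = []
    for (group, i), child in zip(roster, children):
        rng = np.random.default_rng(child)
        pid = f"{group[:3]}{i:02d}"
        participants.append(
            simulate_participant(spec, spec.profiles[group], rng, pid, group)
        )
    return SimulatedCohort(spec=spec, participants=participants)


def write_cohort(cohort: SimulatedCohort, outdir) -> Path:
    """Write a cohort as the CSV file set the analyze pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for p in cohort.participants:
        gz = outdir / f"{p.participant}_gaze.csv"
        hd = outdir / f"{p.participant}_hand.csv"
        mk = outdir / f"{p.participant}_markers.csv"
        write_gaze_table(p.gaze, gz)
        write_hand_table(p.hand, hd)
        write_markers_table(p.markers, mk)
        write_event_table(p.truth_eye, outdir / f"{p.participant}_truth_eye.csv")
        write_event_table(p.truth_hand, outdir / f"{p.participant}_truth_hand.csv")
        manifest.append(
            {
                "participant": p.participant,
                "group": p.group,
                "scenario": p.scenario,
                "gaze_file": gz.name,
                "hand_file": hd.name,
                "markers_file": mk.name,
            }
        )
    pd.DataFrame(manifest).to_csv(outdir / "cohort.csv", index=False)
    write_metrics_table(cohort.planted_records(), outdir / "planted_metrics.csv")
    return outdir
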