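"""End-to-end orchestration: simulate -> align -> classify -> metrics -> stats.

A run is driven by a :class:`RunConfig` (constructible from a YAML mapping),
is deterministic for a given config + seed, writes every intermediate table
as CSV, and ends in a :class:`RunReport` holding the group descriptive
table, the eye-hand correlation battery and group comparisons, plus a
provenance block (config hash, seed, package versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alignment import Session, TaskSegment, align_session
from .errors import GazehandError
from .events import ClassifierConfig, classify_events
from .metrics import METRIC_NAMES, participant_means, summarize, task_metrics
from .simulate import CohortSpec, SimulatedCohort, simulate_cohort, write_cohort
from .stats import CorrelationResult, classify_strength, mann_whitney, run_correlation_battery
from .streams import (
    read_gaze_table,
    read_hand_table,
    read_markers_table,
    write_event_table,
    write_metrics_table,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_report", "analyze_participant"]

log = logging.getLogger("gazehand")


@dataclass
class RunConfig:
    mode: str = "simulate"             # "simulate" | "analyze"
    seed: int | None = 0
    outdir: str = "gazehand_run"
    input_dir: str | None = None       # analyze mode: directory with cohort.csv
    cohort: CohortSpec = field(default_factory=CohortSpec)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    correlation_unit: str = "participant"
    alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "cohort" in data:
            data["cohort"] = CohortSpec(**data["cohort"])
        if "classifier" in data:
            data["classifier"] = ClassifierConfig(**data["classifier"])
        return cls(**data)

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise GazehandError(f"unknown mode {self.mode!r}")
        if self.mode == "simulate" and self.seed is None:
            raise GazehandError("simulate mode requires a seed")
        if self.mode == "analyze":
            if self.input_dir is None:
                raise GazehandError("analyze mode requires input_dir")
            manifest = Path(self.input_dir) / "cohort.csv"
            if not manifest.exists():
                raise GazehandError(f"missing cohort manifest {manifest}")

    def digest(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    summary: pd.DataFrame
    correlations: list[CorrelationResult]
    mw: list[dict]
    provenance: dict

    def correlation_table(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_row() for c in self.correlations])


def analyze_participant(
    gaze, hand, markers: list[TaskSegment],
    classifier: ClassifierConfig = ClassifierConfig(),
    participant: str = "p0",
    scenario: str = "s1",
    offset_ms: float | str = 0.0,
):
    """Align, classify and reduce one session to per-task metric records."""
    session = align_session(gaze, hand, offset_ms=offset_ms)
    eye_events = classify_events(session.gaze, classifier)
    hand_events = classify_events(session.hand, classifier)
    records = [
        task_metrics(eye_events, hand_events, seg, participant, scenario)
        for seg in markers
    ]
    return records, eye_events, hand_events


def _cohort_metrics(cohort: SimulatedCohort, config: RunConfig, outdir: Path) -> pd.DataFrame:
    rows = []
    for p in cohort.participants:
        records, eye_ev, hand_ev = analyze_participant(
            p.gaze, p.hand, p.markers, config.classifier, p.participant, p.scenario
        )
        write_event_table(eye_ev, outdir / f"{p.participant}_events_eye.csv")
        write_event_table(hand_ev, outdir / f"{p.participant}_events_hand.csv")
        rows.extend(r.as_row() for r in records)
        log.info(
            "classified %s: %d eye events, %d hand events, %d tasks",
            p.participant, len(eye_ev.events), len(hand_ev.events), len(records),
        )
    return pd.DataFrame(rows)


def _load_cohort(input_dir: str) -> SimulatedCohort:
    """Read a written cohort directory back into memory (analyze mode)."""
    from .simulate import ParticipantData

    d = Path(input_dir)
    manifest = pd.read_csv(d / "cohort.csv")
    participants = []
    for row in manifest.itertuples():
        participants.append(
            ParticipantData(
                participant=str(row.participant),
                group=str(row.group),
                scenario=str(row.scenario),
                gaze=read_gaze_table(d / row.gaze_file),
                hand=read_hand_table(d / row.hand_file, strict=False),
                markers=read_markers_table(d / row.markers_file),
                truth_eye=None, truth_hand=None, planted=[],
            )
        )
    spec = CohortSpec(
        n_intermediate=sum(p.group == "intermediate" for p in participants),
        n_novice=sum(p.group == "novice" for p in participants),
    )
    return SimulatedCohort(spec=spec, participants=participants)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one full run and write all artifacts under ``config.outdir``."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.mode == "simulate":
        cohort = simulate_cohort(config.cohort, config.seed)
        write_cohort(cohort, outdir / "cohort")
    else:
        cohort = _load_cohort(config.input_dir)

    records = _cohort_metrics(cohort, config, outdir)
    write_metrics_table(records, outdir / "metrics.csv")
    groups = cohort.groups
    summary = summarize(records, groups)
    summary.to_csv(outdir / "summary.csv", index=False)
    correlations = run_correlation_battery(
        records, groups, unit=config.correlation_unit, alpha=config.alpha
    )

    # group comparison on participant-level metric values
    per_part = participant_means(records)
    per_part["group"] = per_part["participant"].map(groups)
    mw_rows = []
    labels = sorted(per_part["group"].unique())
    if len(labels) == 2:
        g1, g2 = labels
        for metric in METRIC_NAMES:
            a = per_part.loc[per_part["group"] == g1, metric].dropna().to_numpy()
            b = per_part.loc[per_part["group"] == g2, metric].dropna().to_numpy()
            if a.size and b.size:
                res = mann_whitney(a, b)
                mw_rows.append(
                    {
                        "metric": metric, "group_1": g1, "group_2": g2,
                        "U": res.U, "z": res.z, "p": res.p,
                        "mean_rank_1": res.mean_rank_1, "mean_rank_2": res.mean_rank_2,
                        "n1": res.n1, "n2": res.n2,
                    }
                )

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "gazehand_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    report = RunReport(
        summary=summary, correlations=correlations, mw=mw_rows, provenance=provenance
    )
    render_report(report, outdir)
    return report


def render_report(report: RunReport, outdir) -> None:
    """Write report.json (machine-readable) and report.md (human-readable)."""
    if report.summary is None or len(report.summary) == 0:
        raise GazehandError("nothing to render: empty report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for c in report.correlations:  # self-consistency of printed labels
        if np.isfinite(c.coefficient):
            assert c.strength == classify_strength(c.coefficient)
    payload = {
        "summary": report.summary.to_dict(orient="records"),
        "correlations": [c.as_row() for c in report.correlations],
        "mann_whitney": report.mw,
        "provenance": report.provenance,
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2))

    lines = ["# gazehand run report", "", "## Descriptive metrics (M / SD per group)", ""]
    lines.append(report.summary.to_string(index=False))
    lines += ["", "## Eye-hand correlations", ""]
    corr = report.correlation_table()
    if len(corr):
        lines.append(
            corr[["group", "pair", "method", "coefficient", "strength", "sign", "p", "n"]]
            .to_string(index=False)
        )
    if report.mw:
        lines += ["", "## Group comparisons (Mann-Whitney U)", ""]
        lines.append(pd.DataFrame(report.mw).to_string(index=False))
    lines += ["", "## Provenance", ""]
    lines += [f"- {k}: {v}" for k, v in report.provenance.items()]
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
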