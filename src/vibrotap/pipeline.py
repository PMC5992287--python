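"""End-to-end pipeline plumbing: run configuration, orchestration, report.

``run_pipeline`` ties the modules into one reproducible run: paradigm
generation -> simulation (or loading an EDF session) -> preprocessing ->
decoding -> assessment -> optional group statistics, writing every
intermediate artifact and a single self-describing JSON report.  Every
stochastic stage takes its seed from the config, and the report embeds the
config hash, so re-running a config reproduces the report byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .assessment import AssessmentConfig, run_assessment
from .edf import read_edf, write_session
from .group_stats import compare_groups
from .paradigm import (LEFT, RIGHT, build_comm_schedule, build_vt2_schedule,
                       build_vt3_schedule, read_events_tsv, write_events_tsv)
from .simulate import SubjectProfile, simulate_session

logger = logging.getLogger("vibrotap")

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration for one end-to-end run.

    Either ``vt2_edf``/``vt3_edf`` point at recorded sessions (with events
    sidecars), or the built-in simulator generates them from ``profile``.
    """

    out_dir: str = "vibrotap_run"
    seed_paradigm: int = 1
    seed_simulation: int = 2
    seed_cv: int = 3
    profile: SubjectProfile = SubjectProfile()
    n_questions: int = 6
    # left = yes, right = no; the simulated subject's intended answers
    intended_answers: tuple[str, ...] = ("yes", "no", "yes", "no", "yes", "no")
    assessment: AssessmentConfig = AssessmentConfig()
    vt2_edf: str | None = None
    vt2_events: str | None = None
    vt3_edf: str | None = None
    vt3_events: str | None = None
    groupstats: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a YAML/JSON run config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "profile" in kwargs:
        kwargs["profile"] = SubjectProfile(**kwargs["profile"])
    if "assessment" in kwargs:
        kwargs["assessment"] = AssessmentConfig(**kwargs["assessment"])
    if "intended_answers" in kwargs:
        kwargs["intended_answers"] = tuple(kwargs["intended_answers"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(kwargs) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)


def _load_session(edf_path, events_path, stage: str):
    edf_path = Path(edf_path)
    if not edf_path.exists():
        raise FileNotFoundError(f"{stage}: EDF file not found: {edf_path}")
    rec = read_edf(edf_path)
    events = None
    if events_path is not None:
        events_path = Path(events_path)
        if not events_path.exists():
            raise FileNotFoundError(
                f"{stage}: events table not found: {events_path}")
        events = read_events_tsv(events_path)
    return rec, events


def run_pipeline(config: RunConfig = RunConfig()) -> dict:
    """Execute the full workflow and return the report dict.

    Artifacts written under ``config.out_dir``: the simulated (or copied
    through) schedules and EDF sessions, and ``report.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seeds": {
            "paradigm": config.seed_paradigm,
            "simulation": config.seed_simulation,
            "cv": config.seed_cv,
        },
        "stages": {},
    }
    asmt_cfg = dataclasses.replace(config.assessment, seed=config.seed_cv)

    events_vt2 = events_vt3 = None
    if config.vt2_edf is not None:
        vt2_rec, events_vt2 = _load_session(config.vt2_edf, config.vt2_events,
                                            "vt2")
        vt3_rec = comm_rec = None
        if config.vt3_edf is not None:
            vt3_rec, events_vt3 = _load_session(config.vt3_edf,
                                                config.vt3_events, "vt3")
        report["stages"]["input"] = {"mode": "edf",
                                     "vt2": str(config.vt2_edf),
                                     "vt3": str(config.vt3_edf)}
    else:
        sched_vt2 = build_vt2_schedule(seed=config.seed_paradigm)
        sched_vt3 = build_vt3_schedule(seed=config.seed_paradigm + 1)
        attended = tuple(LEFT if a == "yes" else RIGHT
                         for a in config.intended_answers)
        sched_comm = build_comm_schedule(
            n_questions=config.n_questions, seed=config.seed_paradigm + 2,
            attended_sites=attended,
        )
        vt2_rec = simulate_session(sched_vt2, config.profile,
                                   seed=config.seed_simulation)
        vt3_rec = simulate_session(sched_vt3, config.profile,
                                   seed=config.seed_simulation + 1)
        comm_rec = simulate_session(sched_comm, config.profile,
                                    seed=config.seed_simulation + 2)
        for name, rec in (("vt2", vt2_rec), ("vt3", vt3_rec),
                          ("comm", comm_rec)):
            write_session(rec, out / f"{name}.edf")
        report["stages"]["input"] = {
            "mode": "simulated",
            "n_stimuli": {"vt2": len(sched_vt2), "vt3": len(sched_vt3),
                          "comm": len(sched_comm)},
            "profile": dataclasses.asdict(config.profile),
        }
        logger.info("simulated sessions: vt2 %d events, vt3 %d, comm %d",
                    len(sched_vt2), len(sched_vt3), len(sched_comm))

    outcome = run_assessment(
        vt2_rec, vt3_rec, comm_rec, config=asmt_cfg,
        events_vt2=events_vt2, events_vt3=events_vt3,
    )
    report["stages"]["assessment"] = outcome.to_dict()
    logger.info("VT2 %.1f%% (rejected %d) -> escalated=%s",
                outcome.vt2.performance_pct, outcome.vt2.n_rejected,
                outcome.escalated)

    if config.groupstats:
        report["stages"]["groupstats"] = {
            g: compare_groups(grouping=g).to_dict() for g in ("crsr", "fdgpet")
        }

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", report_path)
    return report
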