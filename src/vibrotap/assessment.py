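"""Clinical assessment workflow: VT2 -> 70% gate -> VT3 -> communication.

A session is escalated from the two-tactor screening (VT2) to the
three-tactor paradigm (VT3) only when the VT2 detection rate exceeds the
70% communication-feasibility threshold *and* the recording is not
dominated by mechanical artifacts.  The bedside judgment "without
artifacts from the mechanical vibrations" is operationalized as a ceiling
on the rejected-trial fraction (default 50%): a run like the cohort's
UWS-7 — 40% nominal performance with all 480 trials rejected — trips the
flag and is never escalated.  Covert command following is concluded when
the VT3 stage also reaches the threshold (>= at VT3; strictly > at the
VT2 gate, as the screening rule is worded).  Communication blocks are
decoded only after a completed VT3, using an LDA trained on the VT3 data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .decoding import (AnswerResult, PerformanceResult, classify_vt3,
                       crossval_performance, decode_answer, train_lda)
from .preprocessing import REJECTION_THRESHOLD_UV, downsample_features, preprocess
from .simulate import EEGRecording

__all__ = ["AssessmentConfig", "AssessmentOutcome", "run_assessment",
           "passes_gate", "is_covert_cf", "GATE_THRESHOLD_PCT"]

#: minimal performance considered sufficient for effective BCI communication
GATE_THRESHOLD_PCT = 70.0


def passes_gate(vt2_pct: float, artifact_flag: bool = False,
                threshold_pct: float = GATE_THRESHOLD_PCT) -> bool:
    """Screening gate: escalate to VT3 only on strictly-above-threshold VT2
    performance from an artifact-free recording.  NaN never passes."""
    return bool(vt2_pct > threshold_pct) and not artifact_flag


def is_covert_cf(vt3_pct: float | None,
                 threshold_pct: float = GATE_THRESHOLD_PCT) -> bool:
    """Covert command following: the VT3 stage reaches the threshold
    (inclusive — a 70% VT3 run counts)."""
    return vt3_pct is not None and bool(vt3_pct >= threshold_pct)


@dataclass(frozen=True)
class AssessmentConfig:
    gate_threshold_pct: float = GATE_THRESHOLD_PCT
    rejection_threshold_uv: float = REJECTION_THRESHOLD_UV
    artifact_ceiling_frac: float = 0.5
    k_folds: int = 10
    shrinkage: float | str = "auto"
    priors: str = "empirical"
    zero_phase: bool = True
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0


@dataclass
class AssessmentOutcome:
    """Result bundle for one patient assessment.

    Invariants: ``vt3 is not None`` implies the VT2 gate was passed with a
    clean recording; ``covert_cf`` implies the VT3 stage reached the
    threshold too.
    """

    vt2: PerformanceResult
    vt3: PerformanceResult | None
    answers: list[AnswerResult] | None
    escalated: bool
    gate_threshold_pct: float
    artifact_flag: bool
    covert_cf: bool
    status: str = "complete"

    def to_dict(self) -> dict:
        return {
            "vt2": self.vt2.to_dict(),
            "vt3": self.vt3.to_dict() if self.vt3 is not None else None,
            "answers": (
                [asdict(a) for a in self.answers]
                if self.answers is not None else None
            ),
            "escalated": self.escalated,
            "gate_threshold_pct": self.gate_threshold_pct,
            "artifact_flag": self.artifact_flag,
            "covert_cf": self.covert_cf,
            "status": self.status,
        }


def _stage(recording: EEGRecording, events, config: AssessmentConfig,
           label_mode: str):
    epochs, feats = preprocess(
        recording,
        events,
        threshold_uv=config.rejection_threshold_uv,
        zero_phase=config.zero_phase,
        label_mode=label_mode,
    )
    return epochs, feats


def run_assessment(
    session_vt2: EEGRecording,
    session_vt3: EEGRecording | None = None,
    comm_sessions: list[EEGRecording] | EEGRecording | None = None,
    config: AssessmentConfig = AssessmentConfig(),
    events_vt2=None,
    events_vt3=None,
    events_comm=None,
) -> AssessmentOutcome:
    """Run the full threshold-gated workflow on one patient's sessions.

    Communication recordings may be given as one recording whose events
    carry question blocks, or a list of per-question recordings.  The
    outcome is a pure function of the inputs, the config and its seed.
    """
    ep2, feats2 = _stage(session_vt2, events_vt2, config, "deviant")
    artifact_flag = ep2.n_rejected / ep2.n_trials > config.artifact_ceiling_frac
    try:
        vt2 = crossval_performance(
            feats2, k=config.k_folds, seed=config.seed,
            shrinkage=config.shrinkage, priors=config.priors,
            n_rejected=ep2.n_rejected,
        )
    except ValueError:
        # too few retained deviants for CV (heavily artifacted run):
        # performance is undefined and the gate cannot pass
        vt2 = PerformanceResult(
            performance_pct=float("nan"), n_deviant=int(feats2.y.sum()),
            n_rejected=ep2.n_rejected, fold_assignments=np.array([]),
            per_fold_detected=[], per_fold_total=[], seed=config.seed,
            k=config.k_folds,
        )
    escalate = passes_gate(vt2.performance_pct, artifact_flag,
                           config.gate_threshold_pct)

    if not escalate:
        return AssessmentOutcome(
            vt2=vt2, vt3=None, answers=None, escalated=False,
            gate_threshold_pct=config.gate_threshold_pct,
            artifact_flag=artifact_flag, covert_cf=False,
        )
    if session_vt3 is None:
        return AssessmentOutcome(
            vt2=vt2, vt3=None, answers=None, escalated=True,
            gate_threshold_pct=config.gate_threshold_pct,
            artifact_flag=artifact_flag, covert_cf=False,
            status="escalation indicated, data absent",
        )

    ep3, feats3 = _stage(session_vt3, events_vt3, config, "target")
    vt3 = classify_vt3(
        feats3, k=config.k_folds, seed=config.seed,
        shrinkage=config.shrinkage, priors=config.priors,
        n_rejected=ep3.n_rejected,
    )
    covert_cf = is_covert_cf(vt3.performance_pct, config.gate_threshold_pct)

    answers = None
    if comm_sessions is not None:
        model = train_lda(feats3, shrinkage=config.shrinkage,
                          priors=config.priors)
        answers = []
        if isinstance(comm_sessions, EEGRecording):
            comm_sessions = [comm_sessions]
        if events_comm is None:
            events_comm = [None] * len(comm_sessions)
        for s, sess in enumerate(comm_sessions):
            ep, _ = _stage(sess, events_comm[s], config, "deviant")
            if "block" in ep.labels.columns:
                blocks = sorted(ep.labels["block"].unique())
            else:
                blocks = [None]
            for b in blocks:
                block_ep = ep if b is None else ep.select_block(int(b))
                answers.append(decode_answer(
                    block_ep, model, alpha=config.alpha,
                    n_perm=config.n_perm,
                    seed=config.seed + 1000 + 17 * s + int(b or 0),
                ))

    return AssessmentOutcome(
        vt2=vt2, vt3=vt3, answers=answers, escalated=True,
        gate_threshold_pct=config.gate_threshold_pct,
        artifact_flag=artifact_flag, covert_cf=covert_cf,
    )
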