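"""Vibrotactile oddball stimulus schedules.

Three paradigms are generated, matching the bedside protocol of the
mindBEAGLE-style tactile P300 assessment:

* **VT2** — two tactors: frequent standards on the left wrist (7/8) and
  rare deviants on the right wrist (1/8), 480 stimuli at a 300 ms
  stimulus-onset asynchrony (30 ms vibration + 270 ms inter-stimulus
  interval), i.e. a 2.4 min run.  The subject silently counts the
  right-wrist deviants, so every deviant is a target.
* **VT3** — a third tactor on the right foot takes over the standard role
  (6/8); both wrists deliver deviants (1/8 each).  Four blocks of
  15 target-deviant + 15 non-target-deviant + 90 standard trials, with the
  attended wrist assigned per block.
* **COMM** — free communication: per question a 30 s VT3-statistics train;
  attending the left wrist means "yes", the right wrist "no".

Counts are exact (a seeded shuffle of a fixed multiset), not i.i.d. draws,
so every tally is deterministic.  The 225 Hz vibration carrier frequency is
tactor hardware metadata and does not appear in the signal model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusEvent",
    "StimulusSchedule",
    "build_vt2_schedule",
    "build_vt3_schedule",
    "build_comm_schedule",
    "write_events_tsv",
    "read_events_tsv",
    "SOA_S",
    "STIM_DURATION_S",
    "VIBRATION_HZ",
    "ANSWER_MAP",
]

#: default stimulus-onset asynchrony: 30 ms vibration + 270 ms ISI
SOA_S = 0.3
#: mechanical vibration length
STIM_DURATION_S = 0.030
#: tactor carrier frequency (metadata only; not simulated)
VIBRATION_HZ = 225.0

LEFT = "left_wrist"
RIGHT = "right_wrist"
FOOT = "right_foot"
SITES = (LEFT, RIGHT, FOOT)

#: attended-wrist to answer mapping for communication blocks
ANSWER_MAP = {LEFT: "yes", RIGHT: "no"}


@dataclass(frozen=True)
class StimulusEvent:
    """One tactile stimulus.

    Parameters
    ----------
    onset_s : float
        Seconds from run start.
    duration_s : float
        Stimulus length in seconds.
    site : str
        One of ``left_wrist``, ``right_wrist``, ``right_foot``.
    role : str
        ``standard`` or ``deviant``.
    is_target : bool
        True when the deviant is on the attended side under the current
        instruction (the subject is counting it).
    """

    onset_s: float
    duration_s: float
    site: str
    role: str
    is_target: bool

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"onset_s must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be > 0, got {self.duration_s}")
        if self.site not in SITES:
            raise ValueError(f"unknown site {self.site!r}")
        if self.role not in ("standard", "deviant"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.is_target and self.role != "deviant":
            raise ValueError("only deviants can be targets")


@dataclass(frozen=True)
class StimulusSchedule:
    """A timed, typed stimulus sequence for one paradigm run.

    ``blocks`` is a list of ``(start, stop, attended_site)`` with half-open
    event-index ranges; empty for VT2 (the whole run is one implicit block
    attending the right wrist).
    """

    paradigm: str  # VT2 | VT3 | COMM
    events: tuple[StimulusEvent, ...]
    blocks: tuple[tuple[int, int, str], ...]
    seed: int
    soa_s: float = SOA_S

    def __post_init__(self) -> None:
        onsets = [e.onset_s for e in self.events]
        if any(b > a for a, b in zip(onsets[1:], onsets)):
            raise ValueError("events must be sorted by onset")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def duration_s(self) -> float:
        """Total run length: one SOA slot per stimulus."""
        return len(self.events) * self.soa_s

    def tally(self) -> dict[tuple[str, str, bool], int]:
        """Count events by (site, role, is_target)."""
        out: dict[tuple[str, str, bool], int] = {}
        for e in self.events:
            key = (e.site, e.role, e.is_target)
            out[key] = out.get(key, 0) + 1
        return out

    def shifted(self, dt_s: float) -> "StimulusSchedule":
        """Return a copy with every onset shifted by ``dt_s`` seconds."""
        ev = tuple(replace(e, onset_s=e.onset_s + dt_s) for e in self.events)
        return replace(self, events=ev)

    def block_of(self, index: int) -> int:
        """Block id of event ``index`` (-1 if outside every block)."""
        for b, (start, stop, _site) in enumerate(self.blocks):
            if start <= index < stop:
                return b
        return -1

    def to_events_frame(self) -> pd.DataFrame:
        """Events as a BIDS-style table (onset, duration, trial_type, site,
        is_target) plus a ``block`` column when the paradigm has blocks."""
        df = pd.DataFrame(
            {
                "onset": [e.onset_s for e in self.events],
                "duration": [e.duration_s for e in self.events],
                "trial_type": [e.role for e in self.events],
                "site": [e.site for e in self.events],
                "is_target": [int(e.is_target) for e in self.events],
            }
        )
        if self.blocks:
            df["block"] = [self.block_of(i) for i in range(len(self.events))]
        return df


def _assemble(
    paradigm: str,
    per_event: Iterable[tuple[str, str, bool]],
    blocks: Sequence[tuple[int, int, str]],
    soa_s: float,
    seed: int,
    duration_s: float = STIM_DURATION_S,
) -> StimulusSchedule:
    if soa_s <= duration_s:
        raise ValueError(
            f"soa_s ({soa_s}) must exceed the stimulus duration ({duration_s})"
        )
    events = tuple(
        StimulusEvent(k * soa_s, duration_s, site, role, tgt)
        for k, (site, role, tgt) in enumerate(per_event)
    )
    return StimulusSchedule(paradigm, events, tuple(blocks), seed, soa_s)


def build_vt2_schedule(
    n_stimuli: int = 480,
    deviant_fraction: float = 1 / 8,
    soa_s: float = SOA_S,
    seed: int = 0,
) -> StimulusSchedule:
    """Two-tactor oddball: standards on the left wrist, target deviants on
    the right wrist, exactly ``n_stimuli * deviant_fraction`` of them,
    randomly interleaved by ``seed``.
    """
    n_dev_f = n_stimuli * deviant_fraction
    n_dev = int(round(n_dev_f))
    if abs(n_dev_f - n_dev) > 1e-9:
        raise ValueError(
            f"n_stimuli * deviant_fraction = {n_dev_f} is not an integer"
        )
    if not 0 < n_dev < n_stimuli:
        raise ValueError("deviant count must be strictly between 0 and n_stimuli")
    rng = np.random.default_rng(seed)
    roles = np.zeros(n_stimuli, dtype=bool)
    roles[rng.permutation(n_stimuli)[:n_dev]] = True
    per_event = [
        (RIGHT, "deviant", True) if dev else (LEFT, "standard", False)
        for dev in roles
    ]
    return _assemble("VT2", per_event, [], soa_s, seed)


def build_vt3_schedule(
    n_blocks: int = 4,
    per_block: tuple[int, int, int] = (15, 15, 90),
    soa_s: float = SOA_S,
    seed: int = 0,
) -> StimulusSchedule:
    """Three-tactor oddball in attended-wrist blocks.

    Each block holds exactly ``per_block = (targets, nontargets, standards)``
    events: target deviants on the attended wrist, non-target deviants on the
    other wrist, standards on the right foot, shuffled within the block.
    Attended wrists are balanced across blocks (half left, half right,
    rounded arbitrarily for odd ``n_blocks``) in seeded random order.
    """
    n_tgt, n_non, n_std = per_block
    if min(n_tgt, n_non, n_std) <= 0 or n_blocks <= 0:
        raise ValueError("block counts and n_blocks must be positive")
    rng = np.random.default_rng(seed)
    attended = [LEFT] * (n_blocks // 2) + [RIGHT] * (n_blocks - n_blocks // 2)
    attended = [attended[i] for i in rng.permutation(n_blocks)]

    per_event: list[tuple[str, str, bool]] = []
    blocks: list[tuple[int, int, str]] = []
    block_len = n_tgt + n_non + n_std
    for b, att in enumerate(attended):
        other = RIGHT if att == LEFT else LEFT
        pool = (
            [(att, "deviant", True)] * n_tgt
            + [(other, "deviant", False)] * n_non
            + [(FOOT, "standard", False)] * n_std
        )
        order = rng.permutation(block_len)
        per_event.extend(pool[i] for i in order)
        blocks.append((b * block_len, (b + 1) * block_len, att))
    return _assemble("VT3", per_event, blocks, soa_s, seed)


def build_comm_schedule(
    n_questions: int = 6,
    block_duration_s: float = 30.0,
    soa_s: float = SOA_S,
    seed: int = 0,
    attended_sites: Sequence[str] | None = None,
) -> StimulusSchedule:
    """Yes/no communication blocks.

    Each question gets a ``block_duration_s`` train with VT3 statistics:
    ``floor(n/8)`` deviants per wrist, remainder foot standards.  Attending
    the left wrist answers "yes", the right wrist "no" (``ANSWER_MAP``).

    ``attended_sites`` optionally fixes the ground-truth attended wrist per
    question (used by the simulator); deviants on that wrist are then flagged
    as targets.  Without it no event is a target — the subject's intent is
    unknown, which is the situation the decoder faces at the bedside.
    """
    if n_questions <= 0:
        raise ValueError("n_questions must be positive")
    slots = block_duration_s / soa_s
    n_per_block = int(round(slots))
    if abs(slots - n_per_block) > 1e-9 or n_per_block < 1:
        raise ValueError(
            f"block_duration_s ({block_duration_s}) must be a whole number "
            f"of SOA slots ({soa_s} s)"
        )
    if attended_sites is not None:
        if len(attended_sites) != n_questions:
            raise ValueError("attended_sites must give one wrist per question")
        if any(s not in (LEFT, RIGHT) for s in attended_sites):
            raise ValueError("attended_sites entries must be a wrist")

    rng = np.random.default_rng(seed)
    n_dev = n_per_block // 8  # per wrist; remainder are standards
    n_std = n_per_block - 2 * n_dev
    per_event: list[tuple[str, str, bool]] = []
    blocks: list[tuple[int, int, str]] = []
    for q in range(n_questions):
        att = attended_sites[q] if attended_sites is not None else ""
        pool = (
            [(LEFT, "deviant", att == LEFT)] * n_dev
            + [(RIGHT, "deviant", att == RIGHT)] * n_dev
            + [(FOOT, "standard", False)] * n_std
        )
        order = rng.permutation(n_per_block)
        per_event.extend(pool[i] for i in order)
        blocks.append((q * n_per_block, (q + 1) * n_per_block, att))
    return _assemble("COMM", per_event, blocks, soa_s, seed)


def write_events_tsv(schedule: StimulusSchedule, path) -> None:
    """Write the schedule as a UTF-8 tab-separated events table (seconds,
    dot decimal separator, 0-based onsets)."""
    schedule.to_events_frame().to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    """Read an events table written by :func:`write_events_tsv`."""
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "trial_type", "site", "is_target"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return df
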