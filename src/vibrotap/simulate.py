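"""Synthetic oddball EEG sessions.

The simulator stands in for patient recordings so the whole decoding chain
is testable.  The signal model is deliberately minimal — it contains exactly
the structure the P300 decoder exploits and nothing else:

* seeded pink (1/f) background noise per channel,
* a narrowband (8-12 Hz) alpha rhythm, generated as band-limited Gaussian
  noise so it is not phase-locked to the stimulus grid (a fixed 10 Hz
  sinusoid would be: the 300 ms onset asynchrony spans exactly three
  cycles and would then survive trial averaging),
* an additive positive Gaussian bump (the "P3") time-locked to *attended*
  deviant stimuli only, peaking ``p3_latency_s`` after onset inside the
  canonical 300-500 ms window, scaled per channel by a centro-parietal
  topography, and emitted on each trial with probability ``compliance``
  (vigilance fluctuation),
* occasional high-amplitude square bursts emulating mechanical artifacts.

Unattended deviants and standards elicit no evoked response (early
somatosensory components are not modeled).  Units are microvolts throughout
and the mastoid reference is treated as already applied, so the clinical
100 uV rejection threshold applies directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigm import StimulusSchedule

__all__ = ["SubjectProfile", "EEGRecording", "simulate_session", "CHANNELS", "FS_HZ"]

#: default montage, mastoid-referenced active gel electrodes
CHANNELS = ("Fz", "Cz", "C3", "C4", "CPz", "CP1", "CP2", "Pz")
#: default sampling rate
FS_HZ = 256

#: per-channel P3 gain, maximal centro-parietally (Cz/CPz/Pz)
DEFAULT_TOPOGRAPHY = (0.5, 0.9, 0.4, 0.4, 1.0, 0.7, 0.7, 0.9)

#: padding added before the first and after the last stimulus, seconds
EDGE_PAD_S = 1.0

ARTIFACT_DURATION_S = 0.2
ARTIFACT_AMPLITUDE_UV = 300.0  # 3 x the 100 uV rejection threshold


@dataclass(frozen=True)
class SubjectProfile:
    """Parametric description of a simulated subject.

    ``p3_amplitude_uv = 0`` is a non-responder; ``compliance`` is the
    per-trial probability that an attended deviant actually elicits a P3.
    """

    p3_amplitude_uv: float = 5.0
    p3_latency_s: float = 0.35
    p3_width_s: float = 0.06  # Gaussian sigma
    topography: tuple[float, ...] = DEFAULT_TOPOGRAPHY
    noise_sd_uv: float = 5.0
    alpha_amplitude_uv: float = 2.0
    artifact_rate_per_min: float = 0.5
    compliance: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p3_amplitude_uv", "p3_width_s", "noise_sd_uv",
                     "alpha_amplitude_uv", "artifact_rate_per_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.compliance <= 1:
            raise ValueError("compliance must be in [0, 1]")
        if any(not 0 <= g <= 1 for g in self.topography):
            raise ValueError("topography gains must be in [0, 1]")


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG in microvolts.

    ``data`` is channels x samples; ``events`` (if any) is a stimulus
    schedule whose onsets are in this recording's timebase.
    """

    data: np.ndarray
    fs_hz: float = FS_HZ
    channel_names: tuple[str, ...] = CHANNELS
    events: StimulusSchedule | None = None
    reference: str = "mastoids"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channel_names)} "
                "channel names"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz


def _alpha_rhythm(rng: np.random.Generator, n_channels: int, n_samples: int,
                  fs_hz: float) -> np.ndarray:
    """8-12 Hz band-limited Gaussian noise, unit peak-equivalent amplitude
    (RMS = 1/sqrt(2), like a unit sinusoid)."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    band = (freqs >= 8.0) & (freqs <= 12.0)
    spec[:, ~band] = 0.0
    alpha = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = alpha.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return alpha / sd / np.sqrt(2.0)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = 0.0  # no DC
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def simulate_session(
    schedule: StimulusSchedule,
    profile: SubjectProfile = SubjectProfile(),
    seed: int = 0,
    fs_hz: float = FS_HZ,
    channel_names: tuple[str, ...] = CHANNELS,
) -> EEGRecording:
    """Simulate one recording for ``schedule`` under ``profile``.

    The recording covers the schedule plus 1 s padding on both ends; the
    returned recording's ``events`` are the schedule shifted into the
    recording timebase.  Deterministic given (schedule, profile, seed).
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    if len(profile.topography) != len(channel_names):
        raise ValueError("topography length must equal the channel count")

    rng = np.random.default_rng(seed)
    duration_s = schedule.duration_s + 2 * EDGE_PAD_S
    n_samples = int(np.ceil(duration_s * fs_hz))
    n_ch = len(channel_names)
    t = np.arange(n_samples) / fs_hz

    data = np.zeros((n_ch, n_samples))
    if profile.noise_sd_uv > 0:
        data += profile.noise_sd_uv * _pink_noise(rng, n_ch, n_samples)
    if profile.alpha_amplitude_uv > 0:
        data += profile.alpha_amplitude_uv * _alpha_rhythm(
            rng, n_ch, n_samples, fs_hz
        )

    # evoked P3 on attended deviants, per-trial compliance draw
    topo = np.asarray(profile.topography)
    events = schedule.shifted(EDGE_PAD_S)
    if profile.p3_amplitude_uv > 0:
        half_span = 5 * profile.p3_width_s
        for ev in events.events:
            if not ev.is_target:
                continue
            if rng.random() >= profile.compliance:
                continue
            center = ev.onset_s + profile.p3_latency_s
            i0 = max(0, int((center - half_span) * fs_hz))
            i1 = min(n_samples, int((center + half_span) * fs_hz) + 1)
            bump = profile.p3_amplitude_uv * np.exp(
                -0.5 * ((t[i0:i1] - center) / profile.p3_width_s) ** 2
            )
            data[:, i0:i1] += topo[:, None] * bump[None, :]
    else:
        # keep the rng stream aligned across amplitudes at fixed seed
        for ev in events.events:
            if ev.is_target:
                rng.random()

    # mechanical-artifact bursts: Poisson count, uniform placement
    if profile.artifact_rate_per_min > 0:
        expected = profile.artifact_rate_per_min * duration_s / 60.0
        n_art = rng.poisson(expected)
        width = int(ARTIFACT_DURATION_S * fs_hz)
        for onset in rng.uniform(0, duration_s - ARTIFACT_DURATION_S, size=n_art):
            i0 = int(onset * fs_hz)
            data[:, i0 : i0 + width] += ARTIFACT_AMPLITUDE_UV

    return EEGRecording(
        data=data, fs_hz=fs_hz, channel_names=tuple(channel_names), events=events
    )
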