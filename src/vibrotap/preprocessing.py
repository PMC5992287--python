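"""ERP signal chain: band-pass filter, epoching, artifact rejection,
baseline correction, temporal downsampling to the 56-feature matrix.

The chain is fixed:  ``bandpass -> extract_epochs -> reject_artifacts ->
baseline_correct -> downsample_features``.  Epochs run from -100 to 600 ms
around stimulus onset.  At 256 Hz this is realized as 25 pre-onset samples
(~97.7 ms) and 154 post-onset samples (onset sample + 153, ~601.6 ms); 154
was picked because it divides exactly into the 7 required downsampling bins
of 22 samples.  Rejected epochs keep their data but are masked out of every
downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .paradigm import StimulusSchedule
from .simulate import EEGRecording

__all__ = [
    "EpochSet",
    "FeatureMatrix",
    "bandpass",
    "extract_epochs",
    "reject_artifacts",
    "baseline_correct",
    "downsample_features",
    "preprocess",
    "PRE_SAMPLES",
    "POST_SAMPLES",
    "N_BINS",
    "REJECTION_THRESHOLD_UV",
]

PRE_SAMPLES = 25  # floor(0.100 s * 256 Hz)
POST_SAMPLES = 154  # onset sample + 153; 154 = 7 bins x 22 samples
N_BINS = 7
REJECTION_THRESHOLD_UV = 100.0

BAND_LOW_HZ = 0.1
BAND_HIGH_HZ = 30.0
FILTER_ORDER = 4


@dataclass
class EpochSet:
    """Per-stimulus windowed segments with labels and a rejection mask.

    ``epochs`` is trials x channels x samples (uV); ``labels`` carries one
    row per trial (trial_type, site, is_target, block when present);
    ``window = (pre_samples, post_samples)``.  ``rejection_reason`` is ""
    for retained trials, else "edge" or "amplitude".
    """

    epochs: np.ndarray
    labels: pd.DataFrame
    fs_hz: float
    window: tuple[int, int]
    rejected_mask: np.ndarray
    rejection_reason: np.ndarray
    channel_names: tuple[str, ...]
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.rejected_mask) != n:
            raise ValueError("labels/mask length must equal the trial count")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_rejected(self) -> int:
        return int(self.rejected_mask.sum())

    @property
    def n_retained(self) -> int:
        return self.n_trials - self.n_rejected

    def copy(self) -> "EpochSet":
        return replace(
            self,
            epochs=self.epochs.copy(),
            labels=self.labels.copy(),
            rejected_mask=self.rejected_mask.copy(),
            rejection_reason=self.rejection_reason.copy(),
        )

    def subset(self, indices: np.ndarray) -> "EpochSet":
        """Trial subset (e.g. one communication block)."""
        indices = np.asarray(indices)
        return replace(
            self,
            epochs=self.epochs[indices],
            labels=self.labels.iloc[indices].reset_index(drop=True),
            rejected_mask=self.rejected_mask[indices],
            rejection_reason=self.rejection_reason[indices],
        )

    def select_block(self, block: int) -> "EpochSet":
        """Trials belonging to one attended-wrist / question block."""
        if "block" not in self.labels.columns:
            raise ValueError("these epochs carry no block labels")
        return self.subset(np.flatnonzero(self.labels["block"].to_numpy() == block))


@dataclass
class FeatureMatrix:
    """Trials x 56 design matrix for the LDA (7 bin means x 8 channels,
    channel-major), restricted to non-rejected trials.

    ``y`` is the binary class label; ``trial_index`` maps each row back to
    its trial in the originating :class:`EpochSet`.
    """

    X: np.ndarray
    y: np.ndarray
    trial_index: np.ndarray
    labels: pd.DataFrame
    label_mode: str  # 'deviant' or 'target'


def butter_sos(
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
    order: int = FILTER_ORDER,
    fs_hz: float = 256.0,
):
    """Second-order sections of the Butterworth band-pass."""
    if not 0 < low_hz < high_hz < fs_hz / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must sit inside (0, Nyquist)"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs_hz,
                         output="sos")


def bandpass(
    recording: EEGRecording,
    low_hz: float = BAND_LOW_HZ,
    high_hz: float = BAND_HIGH_HZ,
    order: int = FILTER_ORDER,
    zero_phase: bool = True,
) -> EEGRecording:
    """Butterworth band-pass, applied forward-backward by default.

    Zero-phase filtering squares the magnitude response (effective order
    doubles) but leaves component latencies undistorted; ``zero_phase=False``
    gives the causal single-pass filter an online system would use.
    """
    sos = butter_sos(low_hz, high_hz, order, recording.fs_hz)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.data, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.data, axis=1)
    return EEGRecording(
        data=filtered,
        fs_hz=recording.fs_hz,
        channel_names=recording.channel_names,
        events=recording.events,
        reference=recording.reference,
    )


def _events_frame(recording: EEGRecording, events) -> pd.DataFrame:
    if events is None:
        events = recording.events
    if events is None:
        raise ValueError("no events: pass a schedule or events table")
    if isinstance(events, StimulusSchedule):
        return events.to_events_frame()
    return events.reset_index(drop=True)


def extract_epochs(recording: EEGRecording, events=None) -> EpochSet:
    """Cut one epoch per stimulus: samples [onset-25, onset+153] at 256 Hz.

    ``events`` may be a :class:`StimulusSchedule` or a BIDS-style events
    DataFrame; by default the recording's own events are used.  Events too
    close to the recording edge are kept but flagged rejected with reason
    "edge" rather than silently dropped.
    """
    df = _events_frame(recording, events)
    fs = recording.fs_hz
    n_trials = len(df)
    n_ch = recording.data.shape[0]
    width = PRE_SAMPLES + POST_SAMPLES

    epochs = np.zeros((n_trials, n_ch, width))
    mask = np.zeros(n_trials, dtype=bool)
    reason = np.array([""] * n_trials, dtype=object)
    for i, onset in enumerate(df["onset"].to_numpy(dtype=float)):
        onset_sample = int(round(onset * fs))
        i0 = onset_sample - PRE_SAMPLES
        i1 = onset_sample + POST_SAMPLES
        if i0 < 0 or i1 > recording.n_samples:
            mask[i] = True
            reason[i] = "edge"
            continue
        epochs[i] = recording.data[:, i0:i1]

    labels = df[[c for c in ("trial_type", "site", "is_target", "block")
                 if c in df.columns]].copy()
    labels["is_target"] = labels["is_target"].astype(bool)
    return EpochSet(
        epochs=epochs,
        labels=labels,
        fs_hz=fs,
        window=(PRE_SAMPLES, POST_SAMPLES),
        rejected_mask=mask,
        rejection_reason=reason,
        channel_names=recording.channel_names,
    )


def reject_artifacts(
    epochs: EpochSet, threshold_uv: float = REJECTION_THRESHOLD_UV
) -> EpochSet:
    """Mark epochs whose absolute amplitude exceeds ``threshold_uv`` on any
    channel at any sample (data retained under the mask)."""
    out = epochs.copy()
    exceeds = np.abs(out.epochs).max(axis=(1, 2)) > threshold_uv
    newly = exceeds & ~out.rejected_mask
    out.rejected_mask |= exceeds
    out.rejection_reason[newly] = "amplitude"
    return out


def baseline_correct(epochs: EpochSet) -> EpochSet:
    """Subtract the mean of the pre-onset samples, per epoch and channel."""
    pre = epochs.window[0]
    if pre < 1:
        raise ValueError("no pre-onset samples to baseline on")
    out = epochs.copy()
    out.epochs = out.epochs - out.epochs[:, :, :pre].mean(axis=2, keepdims=True)
    out.baseline_corrected = True
    return out


def downsample_features(epochs: EpochSet, label_mode: str = "deviant") -> FeatureMatrix:
    """Bin-mean the 154 post-onset samples into 7 features per channel.

    Features are ordered channel-major (channel 1 bins 1-7, channel 2
    bins 1-7, ...), giving 7 x n_channels columns (56 for the default
    montage).  Only non-rejected trials contribute rows.

    ``label_mode='deviant'`` labels deviant vs standard (VT2);
    ``'target'`` labels target-deviant vs everything else (VT3/COMM).
    """
    if label_mode not in ("deviant", "target"):
        raise ValueError(f"unknown label_mode {label_mode!r}")
    pre, post = epochs.window
    if post % N_BINS != 0:
        raise ValueError(
            f"post-onset window of {post} samples does not divide into "
            f"{N_BINS} bins"
        )
    bin_w = post // N_BINS
    keep = ~epochs.rejected_mask
    idx = np.flatnonzero(keep)
    seg = epochs.epochs[keep][:, :, pre : pre + post]
    n_trials, n_ch = seg.shape[:2]
    # trials x channels x 7 bins -> channel-major flatten
    binned = seg.reshape(n_trials, n_ch, N_BINS, bin_w).mean(axis=3)
    X = binned.reshape(n_trials, n_ch * N_BINS)

    labels = epochs.labels.iloc[idx].reset_index(drop=True)
    if label_mode == "deviant":
        y = (labels["trial_type"] == "deviant").to_numpy()
    else:
        y = labels["is_target"].to_numpy(bool)
    return FeatureMatrix(X=X, y=y.astype(int), trial_index=idx, labels=labels,
                         label_mode=label_mode)


def preprocess(
    recording: EEGRecording,
    events=None,
    threshold_uv: float = REJECTION_THRESHOLD_UV,
    zero_phase: bool = True,
    label_mode: str = "deviant",
) -> tuple[EpochSet, FeatureMatrix]:
    """Run the full fixed chain and return (epochs, features)."""
    filtered = bandpass(recording, zero_phase=zero_phase)
    ep = extract_epochs(filtered, events)
    ep = reject_artifacts(ep, threshold_uv)
    ep = baseline_correct(ep)
    return ep, downsample_features(ep, label_mode)
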