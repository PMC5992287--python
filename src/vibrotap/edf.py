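"""EDF (European Data Format) I/O for continuous sessions.

Writing uses a small self-contained encoder for the classic EDF layout
(fixed-width ASCII header, 16-bit little-endian samples in 1 s data
records); reading goes through :func:`mne.io.read_raw_edf`, which also
acts as an independent check on the writer.  Signals are stored in
microvolts with a symmetric physical range derived from the data, so the
quantization step is ``range / 65535``.

An events sidecar (tab-separated, same dialect as the paradigm module)
can be written next to the EDF; EDF itself carries no event channel here.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .paradigm import write_events_tsv
from .simulate import EEGRecording

__all__ = ["write_edf", "read_edf", "write_session", "EDFFormatError"]


class EDFFormatError(RuntimeError):
    """Raised when a file cannot be parsed as EDF."""


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise EDFFormatError(f"header field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def quantization_step(physical_max_uv: float) -> float:
    """Physical value of one digital step for a symmetric range."""
    return 2 * physical_max_uv / 65535.0


def write_edf(recording: EEGRecording, path) -> float:
    """Write ``recording`` to ``path`` as classic EDF.

    Returns the quantization step (uV per digital unit).  The sampling rate
    must be a whole number (samples per 1 s record); recordings whose length
    is not a whole number of seconds are zero-padded to the next record.
    """
    if recording.n_samples == 0:
        raise EDFFormatError("refusing to write an empty recording")
    fs = recording.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise EDFFormatError(f"EDF writer needs an integer sampling rate, got {fs}")
    fs = int(round(fs))
    for name in recording.channel_names:
        if len(name) > 16:
            raise EDFFormatError(f"channel label {name!r} exceeds 16 characters")

    data = recording.data
    n_ch, n_samp = data.shape
    n_records = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, :n_samp] = data

    phys_max = float(np.ceil(max(1.0, np.max(np.abs(data)) * 1.01)))
    if phys_max >= 10**7:
        raise EDFFormatError("signal amplitude overflows the EDF header width")
    step = quantization_step(phys_max)
    digital = np.clip(
        np.round((padded + phys_max) / step) - 32768, -32768, 32767
    ).astype("<i2")

    start = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _field(0, 8),  # version
            _field("X X X X", 80),  # local patient id (anonymous)
            _field("Startdate X X X X", 80),  # local recording id
            _field(start.strftime("%d.%m.%y"), 8),
            _field(start.strftime("%H.%M.%S"), 8),
            _field(256 * (1 + n_ch), 8),
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),  # record duration, s
            _field(n_ch, 4),
        ]
    )
    header += b"".join(_field(n, 16) for n in recording.channel_names)
    header += b"".join(_field("", 80) for _ in range(n_ch))  # transducer
    header += b"".join(_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{-phys_max:g}", 8) for _ in range(n_ch))
    header += b"".join(_field(f"{phys_max:g}", 8) for _ in range(n_ch))
    header += b"".join(_field(-32768, 8) for _ in range(n_ch))
    header += b"".join(_field(32767, 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))  # prefiltering
    header += b"".join(_field(fs, 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(header)
        # records are channel-sequential within each 1 s chunk
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())
    return step


def read_edf(path) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (microvolts).

    Events are not recovered from the EDF; load the sidecar TSV separately.
    """
    path = Path(path)
    if not path.exists():
        raise EDFFormatError(f"no such file: {path}")
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on bad headers
        raise EDFFormatError(f"cannot parse {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return EEGRecording(
        data=data_uv,
        fs_hz=float(raw.info["sfreq"]),
        channel_names=tuple(raw.ch_names),
        events=None,
    )


def write_session(recording: EEGRecording, edf_path, events_path=None) -> None:
    """Write the EDF plus, when the recording has events, a sidecar TSV
    (default: same stem with ``_events.tsv``)."""
    edf_path = Path(edf_path)
    write_edf(recording, edf_path)
    if recording.events is not None:
        if events_path is None:
            events_path = edf_path.with_name(edf_path.stem + "_events.tsv")
        write_events_tsv(recording.events, events_path)
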