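"""European Data Format (EDF) and seizure-annotation I/O.

Synthetic recordings are exported as plain EDF (16-bit samples, 1-second
data records) with a companion CSV annotation table (columns ``onset_s``,
``offset_s``).  Reading goes through MNE's EDF reader, which also serves as
an independent cross-check of the writer in the test suite.

The writer quantizes each channel to its own physical range, so round-trip
amplitudes agree to within half a quantization step (range / 2^16).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import Recording, SeizureEvent


def _pad(value: str, width: int) -> bytes:
    b = str(value).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path) -> None:
    """Write a recording as EDF with 1-second data records.

    The signal is truncated to a whole number of seconds (EDF stores an
    integral record count); ``fs`` must be integral.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integral sampling rate")
    fs = int(round(fs))
    n_ch = recording.n_channels
    n_records = recording.signal.shape[1] // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    sig = recording.signal[:, : n_records * fs]

    phys_max = np.maximum(np.abs(sig).max(axis=1), 1e-6)
    phys_min = -phys_max
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.rint((sig - phys_min[:, None]) * scale[:, None]) + dig_min, dig_min, dig_max
    ).astype("<i2")

    start = _dt.datetime(2000, 1, 1, 0, 0, 0)
    header_bytes = 256 * (1 + n_ch)
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))  # local patient id (anonymous)
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        f.write(_pad(start.strftime("%d.%m.%y"), 8))
        f.write(_pad(start.strftime("%H.%M.%S"), 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))  # record duration, seconds
        f.write(_pad(str(n_ch), 4))
        names = recording.channel_names or [f"EEG{i + 1:02d}" for i in range(n_ch)]
        for name in names:
            f.write(_pad(name, 16))
        for _ in range(n_ch):
            f.write(_pad("", 80))  # transducer
        for _ in range(n_ch):
            f.write(_pad("uV", 8))
        for v in phys_min:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            f.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(n_ch):
            f.write(_pad(str(dig_min), 8))
        for _ in range(n_ch):
            f.write(_pad(str(dig_max), 8))
        for _ in range(n_ch):
            f.write(_pad("", 80))  # prefiltering
        for _ in range(n_ch):
            f.write(_pad(str(fs), 8))
        for _ in range(n_ch):
            f.write(_pad("", 32))
        # data records: per record, all samples of ch1, then ch2, ...
        records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
        f.write(records.tobytes())


def write_annotations(seizures: list[SeizureEvent], path) -> None:
    """Seizure annotation table: one row per seizure, columns onset_s/offset_s."""
    pd.DataFrame(
        {
            "onset_s": [s.onset for s in seizures],
            "offset_s": [s.offset if s.offset is not None else np.nan for s in seizures],
        }
    ).to_csv(path, index=False)


def read_annotations(path) -> list[SeizureEvent]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        offset = row.get("offset_s")
        offset = None if offset is None or pd.isna(offset) else float(offset)
        out.append(SeizureEvent(onset=float(row["onset_s"]), offset=offset))
    return out


def read_edf(path, annotations_path=None) -> Recording:
    """Load an EDF file (and optional annotation CSV) as a :class:`Recording`.

    Assumes preprocessed (artifact-free) input; amplitudes are returned in
    microvolts.
    """
    import mne

    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # MNE loads volts; recordings are in uV
    seizures = read_annotations(annotations_path) if annotations_path else []
    return Recording(
        signal=signal,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        seizures=seizures,
    )
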