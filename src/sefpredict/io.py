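"""EDF input/output and tabular artifact helpers.

Reading goes through MNE's EDF reader. Writing uses a minimal EDF (16-bit)
writer implemented here, covering the subset of the format this package
produces: one recording per file, integer sampling rate, one-second data
records, physical units of microvolts.
"""
from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np

from .recording import RawRecording

_HEADER_DATE = _dt.datetime(2000, 1, 1, 0, 0, 0)  # fixed -> byte-identical output


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording to EDF (16-bit), truncating to whole seconds.

    Deterministic: the header carries a fixed start date so identical
    recordings produce byte-identical files.
    """
    path = Path(path)
    fs = rec.fs_hz
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * fs]
    ns = rec.n_channels

    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _pad("0", 8),
            _pad(f"X X X {rec.subject_id}", 80),
            _pad(f"Startdate 01-JAN-2000 X X {rec.subject_id}", 80),
            _pad(_HEADER_DATE.strftime("%d.%m.%y"), 8),
            _pad(_HEADER_DATE.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + ns)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    header += b"".join(_pad(lab, 16) for lab in rec.channel_labels)
    header += b"".join(_pad("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(f"{v:.1f}", 8) for v in phys_min)
    header += b"".join(_pad(f"{v:.1f}", 8) for v in phys_max)
    header += b"".join(_pad(str(dig_min), 8) for _ in range(ns))
    header += b"".join(_pad(str(dig_max), 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad(str(fs), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.empty((ns, n_records * fs), dtype="<i2")
    for c in range(ns):
        d = (data[c] - phys_min[c]) * scale[c] + dig_min
        digital[c] = np.clip(np.round(d), dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: for each second, each channel's fs samples in sequence
        blocks = digital.reshape(ns, n_records, fs)
        for r in range(n_records):
            fh.write(blocks[:, r, :].tobytes())
    return path


def read_edf(path: str | Path, subject_id: str | None = None) -> RawRecording:
    """Read an EDF file into a :class:`RawRecording` (µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    sid = subject_id if subject_id is not None else Path(path).stem
    return RawRecording(
        data=data_uv,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        subject_id=sid,
    )
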