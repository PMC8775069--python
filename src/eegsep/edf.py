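"""Minimal EDF (European Data Format) reader/writer.

Supports the plain continuous-EDF subset needed here: one fixed-rate signal
group, 1-second data records, 16-bit samples.  Enough for round-tripping
synthetic cohorts; not a general-purpose EDF implementation (no EDF+
annotations, no discontinuous records).
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Optional

import numpy as np

from .preprocessing import EEGRecording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path,
              patient_id: str = "X", recording_id: str = "synthetic") -> None:
    """Write a recording as continuous 16-bit EDF with 1-s data records.

    Requires an integer sampling rate; a trailing partial second is dropped.
    Physical scaling is per-channel (symmetric around zero).
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record per signal
    ns = rec.n_channels
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one data record")
    data = rec.data[:, : n_records * spr]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    scale = (_DIG_MAX - 1) / phys_max  # keep one LSB of headroom
    digital = np.clip(np.round(data * scale[:, None]), _DIG_MIN, _DIG_MAX
                      ).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (ns + 1)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(ns), 4),
    ])
    per_signal = b"".join([
        b"".join(_field(name, 16) for name in rec.channel_names),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(ns)),
        b"".join(_field("uV", 8) for _ in range(ns)),
        b"".join(_field(f"{-pm:.6g}"[:8], 8) for pm in phys_max),
        b"".join(_field(f"{pm:.6g}"[:8], 8) for pm in phys_max),
        b"".join(_field(str(_DIG_MIN + 1), 8) for _ in range(ns)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(ns)),
        b"".join(_field("", 80) for _ in range(ns)),
        b"".join(_field(str(spr), 8) for _ in range(ns)),
        b"".join(_field("", 32) for _ in range(ns)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + per_signal)
        # records: for each second, all channels' samples sequentially
        rec3 = digital.reshape(ns, n_records, spr)
        for r in range(n_records):
            fh.write(rec3[:, r, :].tobytes())


def read_edf(path: str | Path) -> EEGRecording:
    """Read a continuous EDF file written by :func:`write_edf` (or any plain
    EDF whose signals share one sampling rate)."""
    raw = Path(path).read_bytes()

    def s(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii").strip()

    ns = int(s(252, 4))
    n_records = int(s(236, 8))
    record_dur = float(s(244, 8))
    off = 256
    labels = [s(off + 16 * i, 16) for i in range(ns)]
    off += ns * (16 + 80 + 8)
    phys_min = np.array([float(s(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    phys_max = np.array([float(s(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_min = np.array([float(s(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8
    dig_max = np.array([float(s(off + 8 * i, 8)) for i in range(ns)])
    off += ns * 8 + ns * 80
    spr = np.array([int(s(off + 8 * i, 8)) for i in range(ns)])
    if len(set(spr)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr0 = int(spr[0])
    header_bytes = int(s(184, 8))

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    body = body[: n_records * ns * spr0].reshape(n_records, ns, spr0)
    digital = np.moveaxis(body, 1, 0).reshape(ns, n_records * spr0)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    fs = spr0 / record_dur
    return EEGRecording(data, fs, labels)
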