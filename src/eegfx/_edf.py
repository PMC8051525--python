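"""Minimal writer for standard 16-bit EDF (European Data Format) files.

Only the subset of EDF needed to serialise multichannel voltage series is
implemented: one continuous recording, identical sampling rate on every
signal, physical dimension microvolts. Reading goes through :mod:`mne`.
"""

from __future__ import annotations

import datetime
import math

import numpy as np

_DIG_MIN = -32768
_DIG_MAX = 32767


def _field(value: str, width: int) -> bytes:
    """Left-justified, space-padded ASCII header field."""
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def _fmt_float(x: float, width: int) -> str:
    # fixed-width decimal; fall back to shorter precision until it fits
    for prec in range(6, -1, -1):
        s = f"{x:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {x} in {width} chars")


def write_edf(path, samples: np.ndarray, fs: float, labels, *,
              subject_id: str = "X") -> None:
    """Write ``samples`` (leads x timepoints, microvolts) as 16-bit EDF.

    The recording is split into 1 s data records when the total length is a
    whole number of seconds at an integer ``fs``; otherwise a single data
    record holding the full series is written (legal EDF, record duration
    may be any positive number of seconds).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ValueError("samples must be 2-D (leads x timepoints)")
    n_sig, n_times = samples.shape
    if n_sig == 0:
        raise ValueError("no signals to write")
    if not np.isfinite(samples).all():
        raise ValueError("non-finite sample values")
    labels = [str(l) for l in labels]
    if len(labels) != n_sig:
        raise ValueError("label count does not match signal count")

    fs_int = int(round(fs))
    if math.isclose(fs, fs_int) and n_times % fs_int == 0:
        spr = fs_int                      # samples per record
        n_rec = n_times // fs_int
        rec_dur = 1.0
    else:
        spr = n_times
        n_rec = 1
        rec_dur = n_times / fs

    # symmetric physical range per signal; text-round-tripped so that the
    # scaling a reader recovers from the ASCII header is exactly the one
    # used for quantisation here
    pmax_txt, pmax_val = [], []
    for i in range(n_sig):
        m = float(np.max(np.abs(samples[i]))) or 1.0
        txt = _fmt_float(m, 8)
        pmax_txt.append(txt)
        pmax_val.append(float(txt))

    header_bytes = 256 * (1 + n_sig)
    now = datetime.date(2000, 1, 1)
    head = b"".join([
        _field("0", 8),
        _field(subject_id[:80], 80),
        _field("eegfx recording", 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field("00.00.00", 8),
        _field(str(header_bytes), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field(_fmt_float(rec_dur, 8), 8),
        _field(str(n_sig), 4),
    ])
    per_sig = b"".join([
        b"".join(_field(lab[:16], 16) for lab in labels),
        b"".join(_field("AgAgCl electrode", 80) for _ in range(n_sig)),
        b"".join(_field("uV", 8) for _ in range(n_sig)),
        b"".join(_field("-" + t, 8) for t in pmax_txt),
        b"".join(_field(t, 8) for t in pmax_txt),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_sig)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_sig)),
        b"".join(_field("", 80) for _ in range(n_sig)),
        b"".join(_field(str(spr), 8) for _ in range(n_sig)),
        b"".join(_field("", 32) for _ in range(n_sig)),
    ])

    # quantise with the exact affine map a reader inverts:
    # phys = (dig - dig_min) * (pmax - pmin) / (dig_max - dig_min) + pmin
    dig = np.empty((n_sig, n_times), dtype="<i2")
    for i in range(n_sig):
        p = pmax_val[i]
        gain = 2 * p / (_DIG_MAX - _DIG_MIN)
        scaled = np.round((samples[i] - (-p)) / gain + _DIG_MIN)
        dig[i] = np.clip(scaled, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(per_sig)
        for r in range(n_rec):
            sl = slice(r * spr, (r + 1) * spr)
            for i in range(n_sig):
                fh.write(dig[i, sl].tobytes())
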