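"""Minimal 16-bit EDF writer.

Writes plain (non-annotated) EDF with one-second data records and a
symmetric per-channel physical range, which keeps the quantization step
at range/32767. Reading is delegated to :func:`mne.io.read_raw_edf`;
this module only exists because the pipeline must be able to persist
synthetic cohorts in a standard container.

Recordings must span an integer number of seconds at an integer sampling
rate; the synthetic generator guarantees this, and enforcing it here
avoids silently zero-padding the final data record.
"""

from __future__ import annotations

import numpy as np


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    channel_names: list[str],
    patient_id: str = "X",
    recording_id: str = "X",
) -> None:
    """Write ``data`` (channels x samples, microvolts) as 16-bit EDF."""
    data = np.asarray(data, dtype=float)
    n_ch, n_s = data.shape
    if len(channel_names) != n_ch:
        raise ValueError("channel_names length does not match data")
    if fs != int(fs) or fs <= 0:
        raise ValueError("sampling rate must be a positive integer for EDF export")
    fs = int(fs)
    if n_s % fs:
        raise ValueError("recording must span an integer number of seconds")
    n_rec = n_s // fs

    # symmetric physical range, rounded up so it prints in <= 8 ascii chars
    pmax = np.ceil(np.maximum(np.abs(data).max(axis=1), 1e-6) * 1.05)
    digital = np.round(data / (pmax[:, None] / 32767.0)).astype("<i2")

    hdr = b"".join(
        [
            _field("0", 8),
            _field(patient_id, 80),
            _field(recording_id, 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 * (1 + n_ch), 8),
            _field("", 44),
            _field(n_rec, 8),
            _field("1", 8),
            _field(n_ch, 4),
        ]
    )
    hdr += b"".join(_field(c, 16) for c in channel_names)
    hdr += b"".join(_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_field("uV", 8) for _ in range(n_ch))
    hdr += b"".join(_field("%g" % -p, 8) for p in pmax)
    hdr += b"".join(_field("%g" % p, 8) for p in pmax)
    hdr += b"".join(_field("-32767", 8) for _ in range(n_ch))
    hdr += b"".join(_field("32767", 8) for _ in range(n_ch))
    hdr += b"".join(_field("", 80) for _ in range(n_ch))
    hdr += b"".join(_field(fs, 8) for _ in range(n_ch))
    hdr += b"".join(_field("", 32) for _ in range(n_ch))

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_id_fields(path) -> tuple[str, str]:
    """Return the (patient, recording) identification fields of an EDF header."""
    with open(path, "rb") as fh:
        head = fh.read(168)
    return head[8:88].decode("ascii").strip(), head[88:168].decode("ascii").strip()


def quantization_step(data: np.ndarray) -> float:
    """Worst-case amplitude resolution after a write/read round trip."""
    pmax = np.ceil(np.maximum(np.abs(np.asarray(data)).max(axis=1), 1e-6) * 1.05)
    return float(pmax.max() / 32767.0)
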