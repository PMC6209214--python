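"""Minimal European Data Format (EDF) reader/writer.

Implements the plain EDF container (ASCII header, 16-bit little-endian samples,
one-second data records) — enough to round-trip multichannel µV EEG with 10–20
channel labels. Physical range is fixed at ±3276.8 µV, giving 0.1 µV quantization,
well below the 0.5 µV round-trip tolerance and wide enough for 600 µV artifacts.

No EDF library is available in the target environment, hence this hand-rolled
module; only features the pipeline needs are supported (no annotations, no
discontinuous records, uniform sampling rate across channels).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .segmentation import EEGRecord

PHYS_MAX = 3276.7
PHYS_MIN = -3276.8
DIG_MAX = 32767
DIG_MIN = -32768
_SCALE = (PHYS_MAX - PHYS_MIN) / (DIG_MAX - DIG_MIN)  # 0.1 µV / bit


def _pad(s: str, width: int) -> bytes:
    b = s.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {s!r} (max {width})")
    return b.ljust(width)


def write_edf(record: EEGRecord, path: str | Path) -> None:
    """Write an :class:`EEGRecord` as EDF with one-second data records.

    The record is truncated to a whole number of seconds (with a warning) since
    EDF stores an integral number of fixed-duration records.
    """
    path = Path(path)
    fs = record.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = record.n_samples // spr
    if n_rec * spr != record.n_samples:
        warnings.warn("truncating EDF output to a whole number of 1 s records",
                      stacklevel=2)
    nc = record.n_channels
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (nc + 1)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(nc), 4),
        ]
    )
    fields = [
        [_pad(lab, 16) for lab in record.channel_labels],
        [_pad("AgAgCl electrode", 80)] * nc,
        [_pad("uV", 8)] * nc,
        [_pad(str(PHYS_MIN), 8)] * nc,
        [_pad(str(PHYS_MAX), 8)] * nc,
        [_pad(str(DIG_MIN), 8)] * nc,
        [_pad(str(DIG_MAX), 8)] * nc,
        [_pad("BP:0.5-55Hz", 80)] * nc,
        [_pad(str(spr), 8)] * nc,
        [_pad("", 32)] * nc,
    ]
    sig_header = b"".join(b"".join(f) for f in fields)
    phys = np.clip(record.samples[:, : n_rec * spr], PHYS_MIN, PHYS_MAX)
    dig = np.round((phys - PHYS_MIN) / _SCALE).astype(np.int64) + DIG_MIN
    dig = dig.astype("<i2")
    # records interleave channels: rec0[ch0 spr samples, ch1 ...], rec1[...]
    interleaved = dig.reshape(nc, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(interleaved.tobytes())


def read_edf(path: str | Path) -> EEGRecord:
    """Read an EDF file written by :func:`write_edf` (or any plain uniform-rate EDF)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        nc = int(head[252:256].decode().strip())
        sig = fh.read(256 * nc)
        labels = [sig[16 * i : 16 * (i + 1)].decode().strip() for i in range(nc)]
        off = 16 * nc + 80 * nc + 8 * nc
        phys_min = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(nc)]
        off += 8 * nc
        phys_max = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(nc)]
        off += 8 * nc
        dig_min = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(nc)]
        off += 8 * nc
        dig_max = [float(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(nc)]
        off += 8 * nc + 80 * nc
        spr = [int(sig[off + 8 * i : off + 8 * (i + 1)]) for i in range(nc)]
        if len(set(spr)) != 1:
            raise ValueError("channels with differing sampling rates are not supported")
        raw = np.frombuffer(fh.read(2 * sum(spr) * n_rec), dtype="<i2")
    dig = raw.reshape(n_rec, nc, spr[0]).transpose(1, 0, 2).reshape(nc, -1)
    out = np.empty(dig.shape, dtype=np.float32)
    for c in range(nc):
        gain = (phys_max[c] - phys_min[c]) / (dig_max[c] - dig_min[c])
        out[c] = (dig[c] - dig_min[c]) * gain + phys_min[c]
    return EEGRecord(out, spr[0] / rec_dur, labels)
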