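"""Minimal EDF (16-bit) and BDF (BioSemi 24-bit) reader/writer.

Implements the fixed-width ASCII header plus little-endian integer data
records of the standard interchange formats — enough for round-tripping
continuous multichannel recordings with per-channel physical scaling.
Record duration is fixed at 1 s, so the number of samples must be an
integer multiple of the sampling rate.  Annotations, discontinuous
records and per-channel rates are not supported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

_EDF_DIG = 32767
_BDF_DIG = 8388607


def _fixed(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _physical_range(x: np.ndarray) -> tuple[float, float]:
    amp = float(np.max(np.abs(x))) if x.size else 0.0
    if amp == 0.0:
        amp = 1.0
    # Round *up* to the precision actually stored in the 8-char header
    # field, so digitisation and the reader's rescaling agree exactly
    # and no sample is clipped by the rounding.
    amp = float(f"{amp * (1 + 2e-6):.6g}")
    return -amp, amp


def write_edf(
    path,
    data: np.ndarray,
    rate: float,
    labels,
    bdf: bool = False,
    physical_dim: str = "uV",
) -> None:
    """Write ``(channels, samples)`` data as EDF (or BDF with ``bdf=True``)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = list(labels)
    n_ch, n_s = data.shape
    if n_ch != len(labels):
        raise ValueError(f"{n_ch} channels but {len(labels)} labels")
    spr = int(round(rate))
    if spr != rate or spr <= 0:
        raise ValueError("rate must be a positive integer Hz for EDF/BDF export")
    if n_s % spr != 0:
        raise ValueError(
            f"{n_s} samples is not a whole number of 1 s records at {spr} Hz"
        )
    n_records = n_s // spr
    dig = _BDF_DIG if bdf else _EDF_DIG

    header = bytearray()
    if bdf:
        header += b"\xffBIOSEMI"
    else:
        header += _fixed("0", 8)
    header += _fixed("X X X X", 80)  # local patient id (anonymous)
    header += _fixed("Startdate 01-JAN-2000", 80)
    header += _fixed("01.01.00", 8)
    header += _fixed("00.00.00", 8)
    header += _fixed(str(256 * (1 + n_ch)), 8)
    header += _fixed("24BIT" if bdf else "", 44)
    header += _fixed(str(n_records), 8)
    header += _fixed("1", 8)  # record duration, seconds
    header += _fixed(str(n_ch), 4)

    phys = [_physical_range(data[c]) for c in range(n_ch)]
    for lab in labels:
        header += _fixed(lab, 16)
    header += _fixed("", 80) * n_ch  # transducer
    header += b"".join(_fixed(physical_dim, 8) for _ in range(n_ch))
    header += b"".join(_fixed(f"{lo:.6g}", 8) for lo, _ in phys)
    header += b"".join(_fixed(f"{hi:.6g}", 8) for _, hi in phys)
    header += b"".join(_fixed(str(-dig), 8) for _ in range(n_ch))
    header += b"".join(_fixed(str(dig), 8) for _ in range(n_ch))
    header += _fixed("", 80) * n_ch  # prefiltering
    header += b"".join(_fixed(str(spr), 8) for _ in range(n_ch))
    header += _fixed("", 32) * n_ch

    # Digitize per channel.
    digital = np.empty((n_ch, n_s), dtype=np.int32)
    for c in range(n_ch):
        lo, hi = phys[c]
        scaled = (data[c] - lo) / (hi - lo) * (2 * dig) - dig
        digital[c] = np.clip(np.rint(scaled), -dig, dig).astype(np.int32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            if bdf:
                as32 = block.astype("<i4").tobytes()
                b = np.frombuffer(as32, dtype=np.uint8).reshape(-1, 4)[:, :3]
                fh.write(b.tobytes())
            else:
                fh.write(block.astype("<i2").tobytes())


def read_edf(path) -> tuple[np.ndarray, float, list[str]]:
    """Read an EDF/BDF file written by :func:`write_edf` (or compatible).

    Returns ``(data, rate, labels)`` with data in physical units.
    """
    raw = Path(path).read_bytes()
    magic = raw[:8]
    bdf = magic[0:1] == b"\xff"
    dig = _BDF_DIG if bdf else _EDF_DIG

    def ascii_at(offset: int, width: int) -> str:
        return raw[offset : offset + width].decode("ascii", errors="replace").strip()

    n_records = int(ascii_at(236, 8))
    record_dur = float(ascii_at(244, 8))
    n_ch = int(ascii_at(252, 4))
    off = 256
    labels = [ascii_at(off + 16 * c, 16) for c in range(n_ch)]
    off += n_ch * (16 + 80 + 8)
    phys_min = np.array([float(ascii_at(off + 8 * c, 8)) for c in range(n_ch)])
    off += n_ch * 8
    phys_max = np.array([float(ascii_at(off + 8 * c, 8)) for c in range(n_ch)])
    off += n_ch * 8
    dig_min = np.array([float(ascii_at(off + 8 * c, 8)) for c in range(n_ch)])
    off += n_ch * 8
    dig_max = np.array([float(ascii_at(off + 8 * c, 8)) for c in range(n_ch)])
    off += n_ch * 8 + n_ch * 80
    spr = [int(ascii_at(off + 8 * c, 8)) for c in range(n_ch)]
    if len(set(spr)) != 1:
        raise ValueError("per-channel sampling rates are not supported")
    spr0 = spr[0]
    rate = spr0 / record_dur

    header_bytes = 256 * (1 + n_ch)
    body = raw[header_bytes:]
    bytes_per_sample = 3 if bdf else 2
    record_bytes = n_ch * spr0 * bytes_per_sample
    if len(body) < n_records * record_bytes:
        raise ValueError("truncated EDF/BDF data section")

    data = np.empty((n_ch, n_records * spr0), dtype=float)
    for r in range(n_records):
        chunk = body[r * record_bytes : (r + 1) * record_bytes]
        if bdf:
            b = np.frombuffer(chunk, dtype=np.uint8).reshape(-1, 3)
            as32 = (
                b[:, 0].astype(np.int32)
                | (b[:, 1].astype(np.int32) << 8)
                | (b[:, 2].astype(np.int32) << 16)
            )
            as32 = (as32 << 8) >> 8  # sign-extend 24 -> 32 bit
            block = as32.reshape(n_ch, spr0)
        else:
            block = np.frombuffer(chunk, dtype="<i2").reshape(n_ch, spr0)
        data[:, r * spr0 : (r + 1) * spr0] = block
    # Digital -> physical.
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    data = data * gain[:, None] + (phys_min - dig_min * gain)[:, None]
    if not bdf and dig != _EDF_DIG:  # pragma: no cover - defensive
        raise AssertionError
    return data, rate, labels
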