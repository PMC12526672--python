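"""Minimal EDF writer used only to build test fixtures programmatically.

Writes a spec-conformant EDF file (ASCII headers, 16-bit little-endian
samples, one data record per second). Values survive a round trip only up to
the 16-bit quantisation of the chosen physical range.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _field(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")
    assert len(b) <= width, text
    return b.ljust(width)


def write_edf(path: Path, data: np.ndarray, fs: float,
              channels: list[str]) -> Path:
    """Write (n_channels, n_samples) float data as an EDF file."""
    n_ch, n_samp = data.shape
    assert fs == int(fs) and n_samp % int(fs) == 0
    spr = int(fs)  # samples per 1 s record
    n_rec = n_samp // spr
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),  # patient id
        _field("Startdate X X X X", 80),
        _field("01.01.20", 8), _field("00.00.00", 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_rec), 8),
        _field("1", 8),  # record duration, seconds
        _field(str(n_ch), 4),
    ])
    per_signal = [
        b"".join(_field(f"EEG {c}", 16) for c in channels),
        b"".join(_field("AgAgCl electrode", 80) for _ in channels),
        b"".join(_field("uV", 8) for _ in channels),
        b"".join(_field(str(phys_min), 8) for _ in channels),
        b"".join(_field(str(phys_max), 8) for _ in channels),
        b"".join(_field(str(dig_min), 8) for _ in channels),
        b"".join(_field(str(dig_max), 8) for _ in channels),
        b"".join(_field("", 80) for _ in channels),
        b"".join(_field(str(spr), 8) for _ in channels),
        b"".join(_field("", 32) for _ in channels),
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(np.round((data - phys_min) * scale + dig_min),
                      dig_min, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for block in per_signal:
            fh.write(block)
        for r in range(n_rec):
            for ch in range(n_ch):
                fh.write(digital[ch, r * spr:(r + 1) * spr].tobytes())
    return path
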