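"""Shared fixtures: synthetic recordings and a minimal EDF writer."""

from __future__ import annotations

import struct

import numpy as np
import pytest

from kcdetect import synthetic


@pytest.fixture(scope="session")
def short_recording():
    """20 s / 5 events synthetic recording used by several unit tests."""
    cfg = synthetic.GeneratorConfig(duration=20.0, n_events=5, seed=1)
    return synthetic.generate_recording(cfg)


def write_minimal_edf(path, samples_uv, fs, channel="CZ-A1"):
    """Write a single-channel, single-record EDF file.

    Physical units µV, 16-bit digital range; record duration equals the
    whole signal so the header stays a one-record layout.
    """
    samples_uv = np.asarray(samples_uv, dtype=float)
    n = len(samples_uv)
    phys_min, phys_max = -500.0, 500.0
    dig_min, dig_max = -32768, 32767
    record_dur = n / fs

    def pad(s, width):
        return str(s)[:width].ljust(width)

    header = b"".join(
        pad(x, w).encode("ascii")
        for x, w in [
            ("0", 8), ("X", 80), ("X", 80),
            ("01.01.20", 8), ("00.00.00", 8),
            (str(256 + 256), 8), ("", 44), ("1", 8),
            (f"{record_dur:g}", 8), ("1", 4),
        ]
    )
    ch_header = b"".join(
        pad(x, w).encode("ascii")
        for x, w in [
            (channel, 16), ("AgAgCl electrode", 80), ("uV", 8),
            (f"{phys_min:g}", 8), (f"{phys_max:g}", 8),
            (str(dig_min), 8), (str(dig_max), 8),
            ("", 80), (str(n), 8), ("", 32),
        ]
    )
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((samples_uv - phys_min) * scale + dig_min), dig_min, dig_max
    ).astype(int)
    with open(path, "wb") as fh:
        fh.write(header + ch_header)
        fh.write(struct.pack(f"<{n}h", *digital))
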