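"""Shared fixtures: small signals, synthetic datasets, and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from tensorcsbp import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_signal():
    """The Nc=2, L=9 alternating signal whose features are hand-traceable."""
    return np.array(
        [[1, 0], [0, 1], [2, 0], [0, 2], [3, 0], [0, 3], [4, 0], [0, 4], [5, 0]],
        dtype=float,
    )


@pytest.fixture(scope="session")
def separable_dataset():
    """Default synthetic dataset with class-dependent channel gain (seed 1)."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def emotiv32_montage():
    """A 32-channel frontal-through-occipital 10-20 montage (synthetic stand-in
    for the study cap; the published channel order is not printed)."""
    return [
        "Cz", "Fz", "Fp1", "F7", "F3", "FC1", "C3", "FC5",
        "FT9", "T7", "CP5", "CP1", "P3", "P7", "PO9", "O1",
        "Pz", "Oz", "O2", "PO10", "P8", "P4", "CP2", "CP6",
        "TP10", "T8", "FC6", "C4", "FC2", "F4", "F8", "Fp2",
    ]


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_minimal_edf(
    path: Path,
    channels: list[np.ndarray],
    samples_per_record: list[int],
    labels: list[str],
    phys_dim: str = "uV",
) -> None:
    """Write a minimal synthetic EDF file for read-path tests.

    One-second data records; each channel array's length must be a
    multiple of its samples-per-record and all channels must span the
    same number of records.  16-bit quantization over the per-channel
    physical range, as the format prescribes.
    """
    ns = len(channels)
    n_records = {len(c) // s for c, s in zip(channels, samples_per_record)}
    assert len(n_records) == 1, "channels must span equal record counts"
    n_rec = n_records.pop()

    pmins = [float(np.floor(c.min() - 1)) for c in channels]
    pmaxs = [float(np.ceil(c.max() + 1)) for c in channels]
    dmin, dmax = -32768, 32767

    hdr = b"".join(
        [
            _ascii("0", 8),
            _ascii("synthetic patient", 80),
            _ascii("synthetic recording", 80),
            _ascii("01.01.20", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (1 + ns), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(1, 8),  # record duration, seconds
            _ascii(ns, 4),
        ]
    )
    sig = b"".join(_ascii(lbl, 16) for lbl in labels)
    sig += b"".join(_ascii("synthetic", 80) for _ in range(ns))
    sig += b"".join(_ascii(phys_dim, 8) for _ in range(ns))
    sig += b"".join(_ascii(f"{v:g}", 8) for v in pmins)
    sig += b"".join(_ascii(f"{v:g}", 8) for v in pmaxs)
    sig += b"".join(_ascii(dmin, 8) for _ in range(ns))
    sig += b"".join(_ascii(dmax, 8) for _ in range(ns))
    sig += b"".join(_ascii("", 80) for _ in range(ns))
    sig += b"".join(_ascii(s, 8) for s in samples_per_record)
    sig += b"".join(_ascii("", 32) for _ in range(ns))

    records = bytearray()
    for r in range(n_rec):
        for c, s, lo, hi in zip(channels, samples_per_record, pmins, pmaxs):
            chunk = c[r * s : (r + 1) * s]
            dig = np.round((chunk - lo) / (hi - lo) * (dmax - dmin) + dmin)
            records += struct.pack(f"<{s}h", *dig.astype(np.int16))

    path.write_bytes(hdr + sig + bytes(records))
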