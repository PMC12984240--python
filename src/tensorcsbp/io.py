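"""Reading, validation and segmentation of multichannel EEG recordings.

Recordings are plain numeric matrices oriented time x channels, together
with a sampling rate and an ordered 10-20 channel montage.  No filtering,
re-referencing or artifact rejection is applied anywhere in this module:
the downstream feature extractor consumes raw samples.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np


class EEGIOError(ValueError):
    """Raised for malformed or inconsistent EEG input."""


@dataclass
class EEGRecording:
    """A single multichannel recording.

    Parameters
    ----------
    samples : ndarray, shape (L, Nc)
        Rows are time samples, columns are channels.  Amplitudes are
        microvolt-scale but treated as unitless.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_names : list of str
        One unique 10-20 montage label per column (e.g. ``"F3"``, ``"Cz"``).
    label : hashable, optional
        Class identifier for supervised use.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    label: Hashable | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise EEGIOError(
                f"samples must be a 2-D (time x channels) matrix, got ndim={self.samples.ndim}"
            )
        L, nc = self.samples.shape
        if L < 1 or nc < 1:
            raise EEGIOError(f"empty recording: shape {self.samples.shape}")
        if self.fs <= 0:
            raise EEGIOError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = [str(c) for c in self.channel_names]
        if len(self.channel_names) != nc:
            raise EEGIOError(
                f"{len(self.channel_names)} channel names for {nc} data columns"
            )
        if len(set(self.channel_names)) != nc:
            raise EEGIOError("channel names must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


@dataclass
class SegmentSet:
    """Fixed-length segments cut from one or more recordings.

    All segments share the same shape ``(L, Nc)``, sampling rate and
    montage; ``labels[s]`` is the class of ``segments[s]``.
    """

    segments: list[EEGRecording] = field(default_factory=list)
    labels: list[Hashable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.segments) != len(self.labels):
            raise EEGIOError("segments and labels differ in length")
        if self.segments:
            ref = self.segments[0]
            for i, seg in enumerate(self.segments):
                if seg.samples.shape != ref.samples.shape:
                    raise EEGIOError(
                        f"segment {i} has shape {seg.samples.shape}, "
                        f"expected {ref.samples.shape}"
                    )
                if seg.channel_names != ref.channel_names or seg.fs != ref.fs:
                    raise EEGIOError(f"segment {i} montage or rate mismatch")

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_channels(self) -> int:
        return self.segments[0].n_channels if self.segments else 0

    def extend(self, other: "SegmentSet") -> None:
        self.segments.extend(other.segments)
        self.labels.extend(other.labels)
        self.__post_init__()


def _sniff_delimiter(sample: str) -> str:
    # comma or tab only; decimal point assumed
    try:
        return _csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except _csv.Error:
        return ","


def read_csv_recording(
    path: str | Path,
    fs: float,
    channel_names: Sequence[str] | None = None,
    label: Hashable | None = None,
) -> EEGRecording:
    """Read a delimited numeric table as one recording (rows = time).

    ``channel_names`` may be omitted when the file carries a header row;
    if both are present the explicit names win and must match the column
    count.  Comma and tab delimiters are auto-detected.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EEGIOError(f"{path}: empty file")
    delim = _sniff_delimiter(text[:4096])
    rows = [r for r in _csv.reader(text.splitlines(), delimiter=delim) if r]

    header: list[str] | None = None
    try:
        [float(v) for v in rows[0]]
    except ValueError:
        header = [v.strip() for v in rows[0]]
        rows = rows[1:]
        if not rows:
            raise EEGIOError(f"{path}: header but no data rows")

    ncol = len(rows[0])
    data = np.empty((len(rows), ncol), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != ncol:
            raise EEGIOError(f"{path}: row {i + 1} has {len(row)} cells, expected {ncol}")
        for j, cell in enumerate(row):
            try:
                data[i, j] = float(cell)
            except ValueError:
                raise EEGIOError(
                    f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: {cell!r}"
                ) from None

    names = list(channel_names) if channel_names is not None else header
    if names is None:
        raise EEGIOError(f"{path}: no channel names given and no header row found")
    if len(names) != ncol:
        raise EEGIOError(
            f"{path}: {len(names)} channel names for {ncol} data columns"
        )
    return EEGRecording(samples=data, fs=fs, channel_names=names, label=label)


def _edf_samples_per_record(path: Path) -> list[int]:
    """Per-data-signal samples-per-record from a raw EDF header.

    The EDF header stores fixed-width ASCII fields grouped field-major
    across signals; the samples-per-record block starts 216 bytes per
    signal into the signal header.  EDF+ annotation channels are skipped.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise EEGIOError(f"{path}: truncated EDF header")
        try:
            ns = int(hdr[252:256].decode("ascii").strip())
        except (UnicodeDecodeError, ValueError):
            raise EEGIOError(f"{path}: unreadable EDF header") from None
        sig_hdr = fh.read(ns * 256)
    labels = [
        sig_hdr[i * 16 : (i + 1) * 16].decode("ascii", "replace").strip()
        for i in range(ns)
    ]
    off = ns * 216  # label/transducer/unit/phys+dig ranges/prefilter precede
    fields = sig_hdr[off : off + ns * 8]
    return [
        int(fields[i * 8 : (i + 1) * 8].decode("ascii").strip())
        for i in range(ns)
        if labels[i] != "EDF Annotations"
    ]


def read_edf_recording(path: str | Path, label: Hashable | None = None) -> EEGRecording:
    """Read an EDF/EDF+ file; all signals must share one sampling rate.

    Channel names come from the EDF signal labels and samples are
    transposed to time x channel.  Annotation channels are dropped.
    """
    import mne

    path = Path(path)
    spr = _edf_samples_per_record(path)
    data_spr = [s for s in spr]
    if len(set(data_spr)) > 1:
        raise EEGIOError(
            f"{path}: mixed per-signal sampling rates {sorted(set(data_spr))} are unsupported"
        )
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises several concrete types
        raise EEGIOError(f"{path}: cannot read EDF: {exc}") from exc
    data = raw.get_data()  # channels x time, in volts for EEG-typed channels
    return EEGRecording(
        samples=data.T,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        label=label,
    )


def segment_recording(rec: EEGRecording, seg_seconds: float) -> SegmentSet:
    """Cut a recording into consecutive non-overlapping fixed-length windows.

    Window length is ``L = seg_seconds * fs`` samples, which must be a
    positive integer.  A trailing remainder shorter than ``L`` is discarded,
    never zero-padded.  Each segment inherits ``fs``, montage and label.
    A recording shorter than one window yields an empty set.
    """
    L_float = seg_seconds * rec.fs
    L = int(round(L_float))
    if L <= 0 or abs(L_float - L) > 1e-9:
        raise EEGIOError(
            f"seg_seconds * fs must be a positive integer, got {L_float}"
        )
    n = rec.n_samples // L
    segments = [
        EEGRecording(
            samples=rec.samples[i * L : (i + 1) * L],
            fs=rec.fs,
            channel_names=rec.channel_names,
            label=rec.label,
        )
        for i in range(n)
    ]
    return SegmentSet(segments=segments, labels=[rec.label] * n)
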