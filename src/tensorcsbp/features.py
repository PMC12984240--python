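"""Center-symmetric rank-transition feature extraction for multichannel signals.

The extractor slides an 8-sample window over the time axis with unit step.
Within each window it forms the four center-symmetric difference vectors
``D_k = V_k - V_{9-k}`` (``k`` = 1..4) across channels, replaces each
difference vector by the descending argsort of its channel values (a
permutation of 1..Nc), and concatenates the permutations over windows into
four integer sequences.  Counting adjacent ordered symbol pairs of each
sequence yields four Nc x Nc transition matrices whose row-major
flattenings, concatenated, form the final feature vector of length
``4 * Nc**2``.

Because only the ordering of channel values enters the features, the
extractor is exactly invariant under ``a * signal + b`` for any ``a > 0``
and scalar ``b`` applied to the whole matrix; class information must be
channel-differential to be visible.
"""

from __future__ import annotations

import numpy as np

from .io import SegmentSet

WINDOW = 8  # samples per window; fixed by the center-symmetric pairing
N_DIFF = 4  # difference vectors per window


class FeatureExtractionError(ValueError):
    """Raised for inputs the extractor cannot process."""


def _as_signal(signal: np.ndarray) -> np.ndarray:
    sig = np.asarray(signal, dtype=float)
    if sig.ndim != 2:
        raise FeatureExtractionError(f"signal must be 2-D, got ndim={sig.ndim}")
    if sig.shape[0] < WINDOW:
        raise FeatureExtractionError(
            f"signal has {sig.shape[0]} samples; at least {WINDOW} are required"
        )
    return sig


def make_windows(signal: np.ndarray) -> np.ndarray:
    """All overlapping 8-row windows of the signal, step one sample.

    Returns an array of shape ``(W, 8, Nc)`` with ``W = L - 7``; window
    ``w`` holds sample rows ``w .. w+7`` (0-based).
    """
    sig = _as_signal(signal)
    W = sig.shape[0] - WINDOW + 1
    return np.stack([sig[i : i + W] for i in range(WINDOW)], axis=1)


def center_symmetric_differences(window: np.ndarray) -> np.ndarray:
    """The four center-symmetric differences of one 8-row window.

    ``D_k = V_k - V_{9-k}`` (1-based), i.e. row 0 minus row 7, row 1 minus
    row 6, row 2 minus row 5, row 3 minus row 4; shape ``(4, Nc)``.
    """
    win = np.asarray(window, dtype=float)
    if win.shape[0] != WINDOW:
        raise FeatureExtractionError(f"window must have {WINDOW} rows, got {win.shape[0]}")
    return win[:N_DIFF] - win[WINDOW - 1 : N_DIFF - 1 : -1]


def rank_transform(d: np.ndarray) -> np.ndarray:
    """1-based channel indices of a vector sorted by descending value.

    Ties break toward the smaller channel index (stable descending sort)
    so the transform is deterministic on constant or repeated inputs.
    """
    d = np.asarray(d, dtype=float)
    if np.isnan(d).any():
        raise FeatureExtractionError("NaN in difference vector")
    return np.argsort(-d, kind="stable") + 1


def build_transformed_signals(signal: np.ndarray) -> np.ndarray:
    """The four rank-transformed integer sequences of a signal.

    Returns an int array of shape ``(4, Nc * W)``; sequence ``k`` is the
    concatenation, window by window in time order, of the descending
    argsort of ``D_k``.  Every consecutive Nc-block is a permutation of
    ``1..Nc``.
    """
    sig = _as_signal(signal)
    L, nc = sig.shape
    W = L - WINDOW + 1
    # D[k] over all windows at once: rows k .. k+W-1 minus rows (7-k) .. (7-k)+W-1
    out = np.empty((N_DIFF, nc * W), dtype=np.int64)
    for k in range(N_DIFF):
        diffs = sig[k : k + W] - sig[WINDOW - 1 - k : WINDOW - 1 - k + W]  # (W, Nc)
        if np.isnan(diffs).any():
            raise FeatureExtractionError("NaN in difference vectors")
        ranks = np.argsort(-diffs, axis=1, kind="stable") + 1
        out[k] = ranks.reshape(-1)
    return out


def transition_matrix(seq: np.ndarray, nc: int) -> np.ndarray:
    """Counts of adjacent ordered pairs in an integer sequence over 1..nc.

    Entry ``(r, c)`` (1-based symbols) counts occurrences of symbol ``r``
    immediately followed by symbol ``c``; the total count is
    ``len(seq) - 1``.  Adjacency spans the whole sequence, including
    window boundaries when applied to a concatenated rank sequence.
    """
    seq = np.asarray(seq)
    if seq.size < 1:
        raise FeatureExtractionError("sequence must be non-empty")
    bad = (seq < 1) | (seq > nc)
    if bad.any():
        pos = int(np.argmax(bad))
        raise FeatureExtractionError(
            f"symbol {seq[pos]} at position {pos} outside 1..{nc}"
        )
    tm = np.zeros((nc, nc), dtype=np.int64)
    np.add.at(tm, (seq[:-1] - 1, seq[1:] - 1), 1)
    return tm


def extract_features(signal: np.ndarray) -> np.ndarray:
    """Final feature vector of one signal: length ``4 * Nc**2``.

    Concatenates the row-major flattenings of the four transition
    matrices in order.  Entries are raw non-negative integer counts; no
    normalization is applied here.
    """
    sig = _as_signal(signal)
    nc = sig.shape[1]
    T = build_transformed_signals(sig)
    return np.concatenate(
        [transition_matrix(T[k], nc).reshape(-1) for k in range(N_DIFF)]
    )


def extract_feature_matrix(segments: SegmentSet) -> np.ndarray:
    """Feature matrix ``X`` of shape ``(Ns, 4 * Nc**2)``, one row per segment."""
    rows = []
    for i, seg in enumerate(segments.segments):
        try:
            rows.append(extract_features(seg.samples))
        except FeatureExtractionError as exc:
            raise FeatureExtractionError(f"segment {i}: {exc}") from exc
    if not rows:
        return np.empty((0, 0), dtype=np.int64)
    return np.vstack(rows)
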