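"""Directed Lobish (DLob) symbolic explainability.

Selected feature indices are decoded back to the pair of EEG channels
whose rank transition produced the feature, each channel is mapped to a
two-letter brain-region symbol (lobe letter + hemisphere letter, e.g.
``FL`` = left frontal, ``Pz`` = midline parietal), and the resulting
symbol sequence is summarized with histograms, transition (connectome)
matrices, Shannon entropy and entropy-based complexity ratios.  A
parallel hemispheric sequence over ``{L, R, z}`` is obtained from the
second letter of every symbol.
"""

from __future__ import annotations

import json
import math
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: The full 16-symbol alphabet: F/T/C/P/O lobes plus auditory, each with
#: left / right / midline variants (auditory has no midline symbol).
ALPHABET: tuple[str, ...] = (
    "FL", "FR", "Fz",
    "TL", "TR",
    "CL", "CR", "Cz",
    "PL", "PR", "Pz",
    "OL", "OR", "Oz",
    "AL", "AR",
)

HEMISPHERES: tuple[str, ...] = ("L", "R", "z")

#: Utilized alphabet sizes for complexity denominators: a 32-channel
#: frontal-through-occipital cap reaches 14 of the 16 symbols (no
#: dedicated auditory electrodes), and 3 hemispheric symbols.
DLOB_ALPHABET_SIZE = 14
HEMI_ALPHABET_SIZE = 3

_DATA_DIR = Path(__file__).parent / "data"


class DLobError(ValueError):
    """Raised for invalid symbols, indices or LUTs."""


# ---------------------------------------------------------------------------
# Channel look-up table


def symbol_for_channel(name: str) -> str:
    """Map one 10-20 channel label to its brain-region symbol.

    The lobe letter comes from the label prefix (Fp/AF/F/FC/FT -> F,
    T/TP -> T, C/CP -> C, P/PO -> P, O -> O) and the hemisphere from the
    digit parity (odd -> L, even -> R) or a trailing ``z`` (midline).
    """
    m = re.fullmatch(r"([A-Za-z]+)(\d+|z|Z)", name.strip())
    if not m:
        raise DLobError(f"cannot parse channel label {name!r}")
    prefix, suffix = m.group(1), m.group(2)
    prefix_map = {
        "FP": "F", "AF": "F", "F": "F", "FC": "F", "FT": "F",
        "T": "T", "TP": "T",
        "C": "C", "CP": "C",
        "P": "P", "PO": "P",
        "O": "O",
        "A": "A",
    }
    lobe = prefix_map.get(prefix.upper())
    if lobe is None:
        raise DLobError(f"unknown lobe prefix {prefix!r} in channel {name!r}")
    if suffix.lower() == "z":
        hemi = "z"
    else:
        hemi = "L" if int(suffix) % 2 == 1 else "R"
    symbol = lobe + hemi
    if symbol not in ALPHABET:
        raise DLobError(f"channel {name!r} maps to {symbol!r}, not a valid symbol")
    return symbol


@dataclass
class ChannelLUT:
    """Channel-to-symbol look-up table for one montage.

    ``symbols[i]`` is the region symbol of 1-based channel ``i + 1``.
    """

    channel_names: list[str]
    symbols: list[str]

    def __post_init__(self) -> None:
        if len(self.channel_names) != len(self.symbols):
            raise DLobError("one symbol per channel required")
        bad = [s for s in self.symbols if s not in ALPHABET]
        if bad:
            raise DLobError(f"symbols outside the alphabet: {bad}")

    @classmethod
    def from_montage(cls, channel_names: Sequence[str]) -> "ChannelLUT":
        """Auto-build from 10-20 labels via :func:`symbol_for_channel`."""
        return cls(
            channel_names=list(channel_names),
            symbols=[symbol_for_channel(c) for c in channel_names],
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "ChannelLUT":
        """Read a two-column delimited file of ``channel_name  symbol`` rows."""
        names, symbols = [], []
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"[,\t\s]+", line)
            if len(parts) != 2:
                raise DLobError(f"{path}:{ln}: expected two columns, got {line!r}")
            names.append(parts[0])
            symbols.append(parts[1])
        return cls(channel_names=names, symbols=symbols)

    def symbol(self, channel_1based: int) -> str:
        if not 1 <= channel_1based <= len(self.symbols):
            raise DLobError(
                f"channel {channel_1based} outside montage of {len(self.symbols)}"
            )
        return self.symbols[channel_1based - 1]

    def __len__(self) -> int:
        return len(self.symbols)


# ---------------------------------------------------------------------------
# Sequence construction


def feature_index_to_channels(f: int, nc: int) -> tuple[int, int]:
    """Decode a 1-based feature index into its (row, col) channel pair.

    Features are the row-major flattenings of four Nc x Nc transition
    matrices concatenated; the modulo collapses all four onto one channel
    grid, so indices ``f``, ``f + Nc**2``, ``f + 2*Nc**2`` and
    ``f + 3*Nc**2`` decode identically.  Channels are returned 1-based.
    """
    if not 1 <= f <= 4 * nc * nc:
        raise DLobError(f"feature index {f} outside 1..{4 * nc * nc}")
    row = ((f - 1) // nc) % nc + 1
    col = (f - 1) % nc + 1
    return row, col


def generate_symbol_sequence(
    selected_indices_1based: Iterable[int], lut: ChannelLUT, nc: int
) -> list[str]:
    """Symbol sequence of a selection: two symbols per selected feature.

    For each feature index (in selection order) the row channel's symbol
    is emitted first, then the column channel's; total length is twice
    the number of selected features.
    """
    seq: list[str] = []
    for f in selected_indices_1based:
        row, col = feature_index_to_channels(int(f), nc)
        seq.append(lut.symbol(row))
        seq.append(lut.symbol(col))
    return seq


def tokenize_sentence(text: str) -> list[str]:
    """Split a concatenated symbol string into two-character symbols."""
    text = text.strip()
    if len(text) % 2 != 0:
        raise DLobError(f"sentence length {len(text)} is odd; symbols are 2 characters")
    seq = []
    for i in range(0, len(text), 2):
        tok = text[i : i + 2]
        if tok not in ALPHABET:
            raise DLobError(f"invalid symbol {tok!r} at offset {i}")
        seq.append(tok)
    return seq


def hemispheric_sequence(seq: Sequence[str]) -> list[str]:
    """The second letter (L/R/z) of every symbol, order preserved."""
    return [s[1] for s in seq]


# ---------------------------------------------------------------------------
# Sequence statistics


def sequence_histogram(
    seq: Sequence[str], alphabet: Sequence[str] | None = None
) -> dict[str, int]:
    """Occurrence counts per symbol; absent alphabet symbols count 0."""
    counts = Counter(seq)
    if alphabet is None:
        alphabet = sorted(counts)
    return {s: counts.get(s, 0) for s in alphabet}


def sequence_transition_matrix(
    seq: Sequence[str], alphabet: Sequence[str]
) -> np.ndarray:
    """Counts of consecutive ordered symbol pairs; total = length - 1."""
    index = {s: i for i, s in enumerate(alphabet)}
    tm = np.zeros((len(alphabet), len(alphabet)), dtype=np.int64)
    prev = None
    for pos, s in enumerate(seq):
        if s not in index:
            raise DLobError(f"symbol {s!r} at position {pos} outside the alphabet")
        if prev is not None:
            tm[index[prev], index[s]] += 1
        prev = s
    return tm


def shannon_entropy(seq: Sequence[str]) -> float:
    """Shannon entropy of the empirical symbol distribution, in bits."""
    n = len(seq)
    if n == 0:
        raise DLobError("entropy of an empty sequence is undefined")
    counts = np.array(list(Counter(seq).values()), dtype=float)
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def complexity_ratio(seq: Sequence[str], alphabet_size: int) -> float:
    """Entropy normalized by the maximal entropy ``log2(alphabet_size)``."""
    if alphabet_size < 2:
        raise DLobError("alphabet size must be at least 2")
    return shannon_entropy(seq) / math.log2(alphabet_size)


# ---------------------------------------------------------------------------
# Report


@dataclass
class XAIReport:
    """All symbolic statistics of one DLob / hemispheric sequence pair."""

    symbol_sequence: list[str]
    hemispheric: list[str]
    symbol_histogram: dict[str, int]
    hemispheric_histogram: dict[str, int]
    symbol_transitions: np.ndarray
    hemispheric_transitions: np.ndarray
    symbol_entropy: float
    hemispheric_entropy: float
    symbol_complexity: float
    hemispheric_complexity: float
    symbol_alphabet: list[str] = field(default_factory=lambda: list(ALPHABET))
    #: Hemisphere totals are symbol-occurrence counts (they sum to the
    #: sequence length); cross-talk is the count of consecutive L->R and
    #: R->L pairs in the hemispheric sequence.
    notes: str = (
        "hemispheric totals are occurrence counts; cross-talk counts are "
        "consecutive L/R transition counts"
    )

    @property
    def cross_hemispheric_transitions(self) -> tuple[int, int]:
        """(L->R, R->L) consecutive-pair counts in the hemispheric sequence."""
        hm = {h: i for i, h in enumerate(HEMISPHERES)}
        tm = self.hemispheric_transitions
        return int(tm[hm["L"], hm["R"]]), int(tm[hm["R"], hm["L"]])

    def to_dict(self) -> dict:
        return {
            "sequence_length": len(self.symbol_sequence),
            "symbol_histogram": self.symbol_histogram,
            "hemispheric_histogram": self.hemispheric_histogram,
            "symbol_transitions": self.symbol_transitions.tolist(),
            "hemispheric_transitions": self.hemispheric_transitions.tolist(),
            "symbol_entropy": self.symbol_entropy,
            "hemispheric_entropy": self.hemispheric_entropy,
            "symbol_complexity": self.symbol_complexity,
            "hemispheric_complexity": self.hemispheric_complexity,
            "cross_hemispheric_transitions": list(self.cross_hemispheric_transitions),
            "notes": self.notes,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def connectome_graph(self, hemispheric: bool = False):
        """Directed weighted symbol-transition graph (networkx DiGraph)."""
        import networkx as nx

        alphabet = list(HEMISPHERES) if hemispheric else self.symbol_alphabet
        tm = self.hemispheric_transitions if hemispheric else self.symbol_transitions
        g = nx.DiGraph()
        for i, a in enumerate(alphabet):
            for j, b in enumerate(alphabet):
                if tm[i, j] > 0:
                    g.add_edge(a, b, weight=int(tm[i, j]))
        return g


def analyze_sequence(
    seq: Sequence[str],
    symbol_alphabet_size: int = DLOB_ALPHABET_SIZE,
    hemispheric_alphabet_size: int = HEMI_ALPHABET_SIZE,
) -> XAIReport:
    """Full symbolic report of one symbol sequence."""
    hemi = hemispheric_sequence(seq)
    return XAIReport(
        symbol_sequence=list(seq),
        hemispheric=hemi,
        symbol_histogram=sequence_histogram(seq, ALPHABET),
        hemispheric_histogram=sequence_histogram(hemi, HEMISPHERES),
        symbol_transitions=sequence_transition_matrix(seq, ALPHABET),
        hemispheric_transitions=sequence_transition_matrix(hemi, HEMISPHERES),
        symbol_entropy=shannon_entropy(seq),
        hemispheric_entropy=shannon_entropy(hemi),
        symbol_complexity=complexity_ratio(seq, symbol_alphabet_size),
        hemispheric_complexity=complexity_ratio(hemi, hemispheric_alphabet_size),
    )


def published_sentence(which: str = "dlob") -> str:
    """The published odor-study symbol sentences shipped with the package.

    ``which`` is ``"dlob"`` (two-letter region symbols) or
    ``"hemispheric"`` (single letters L/R/z).
    """
    fname = {"dlob": "dlob_sentence.txt", "hemispheric": "hemispheric_sentence.txt"}
    if which not in fname:
        raise DLobError(f"unknown sentence {which!r}")
    return (_DATA_DIR / fname[which]).read_text().strip()
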