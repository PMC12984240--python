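"""End-to-end orchestration: extraction, selection, classification, explanation.

``run_pipeline`` wires the four phases together from a single config and
writes JSON/CSV reports plus a provenance block; ``analyze_sentence``
runs the symbolic statistics directly on a stored symbol sentence.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .classify import MetricReport, OutcomeSet, ParameterBag, confusion_metrics, run_tknn
from .dlob import (
    DLOB_ALPHABET_SIZE,
    HEMI_ALPHABET_SIZE,
    ChannelLUT,
    XAIReport,
    analyze_sequence,
    generate_symbol_sequence,
    tokenize_sentence,
)
from .features import extract_feature_matrix
from .io import SegmentSet
from .selection import DEFAULT_THRESHOLD, SelectionResult, select_features
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger("tensorcsbp")


@dataclass
class PipelineConfig:
    """Settings for one full pipeline run."""

    threshold: float = DEFAULT_THRESHOLD
    folds: int = 10
    seed: int = 1
    bag: ParameterBag = field(default_factory=ParameterBag)
    lut_path: str | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    selection: SelectionResult
    outcomes: OutcomeSet
    metrics: MetricReport
    xai: XAIReport
    provenance: dict

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "selection.json").write_text(
            json.dumps(self.selection.to_dict(), indent=2)
        )
        (out_dir / "outcomes.json").write_text(
            json.dumps(self.outcomes.to_dict(), indent=2)
        )
        (out_dir / "metrics.json").write_text(
            json.dumps(self.metrics.to_dict(), indent=2)
        )
        self.xai.to_json(out_dir / "xai.json")
        np.savetxt(
            out_dir / "confusion.csv", self.metrics.confusion, fmt="%d", delimiter=","
        )
        (out_dir / "provenance.json").write_text(json.dumps(self.provenance, indent=2))
        return out_dir


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(
        {
            "threshold": cfg.threshold,
            "folds": cfg.folds,
            "seed": cfg.seed,
            "bag": asdict(cfg.bag),
        },
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(
    segments: SegmentSet,
    cfg: PipelineConfig | None = None,
    lut: ChannelLUT | None = None,
) -> PipelineReport:
    """Run extraction -> selection -> ensemble classification -> explanation.

    The explanation decodes the selected feature indices of the whole
    dataset into channel-pair symbols via the montage LUT (auto-built
    from the 10-20 channel names unless one is supplied).
    """
    cfg = cfg or PipelineConfig()
    nc = segments.n_channels
    if lut is None:
        if cfg.lut_path:
            lut = ChannelLUT.from_file(cfg.lut_path)
        else:
            lut = ChannelLUT.from_montage(segments.segments[0].channel_names)

    timings = {}
    t0 = time.perf_counter()
    try:
        X = extract_feature_matrix(segments)
    except Exception as exc:
        raise RuntimeError(f"extraction phase failed: {exc}") from exc
    timings["extract_s"] = time.perf_counter() - t0
    logger.info("extracted %s features from %s segments", X.shape[1], X.shape[0])

    y = np.asarray(segments.labels)
    t0 = time.perf_counter()
    try:
        sel = select_features(X, y, th=cfg.threshold)
    except Exception as exc:
        raise RuntimeError(f"selection phase failed: {exc}") from exc
    timings["select_s"] = time.perf_counter() - t0
    logger.info("selected %d / %d features", sel.n_selected, X.shape[1])

    t0 = time.perf_counter()
    try:
        outcomes = run_tknn(
            sel.selected_matrix, y, bag=cfg.bag, folds=cfg.folds, seed=cfg.seed
        )
    except Exception as exc:
        raise RuntimeError(f"classification phase failed: {exc}") from exc
    timings["classify_s"] = time.perf_counter() - t0
    metrics = confusion_metrics(y, outcomes.final_labels())
    logger.info(
        "best of %d outcomes: accuracy %.4f", outcomes.n_outcomes, outcomes.final_acc
    )

    t0 = time.perf_counter()
    try:
        n_symbols = len(set(lut.symbols))
        seq = generate_symbol_sequence(sel.selected_indices_1based, lut, nc)
        xai = analyze_sequence(
            seq,
            symbol_alphabet_size=max(2, n_symbols),
            hemispheric_alphabet_size=HEMI_ALPHABET_SIZE,
        )
    except Exception as exc:
        raise RuntimeError(f"explanation phase failed: {exc}") from exc
    timings["explain_s"] = time.perf_counter() - t0

    provenance = {
        "version": __version__,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "folds": cfg.folds,
        "threshold": cfg.threshold,
        "n_segments": segments.n_segments,
        "n_channels": nc,
        "timings": timings,
    }
    report = PipelineReport(
        selection=sel, outcomes=outcomes, metrics=metrics, xai=xai,
        provenance=provenance,
    )
    if cfg.output_dir:
        report.write(cfg.output_dir)
    return report


def run_synthetic_pipeline(
    syn: SyntheticConfig | None = None, cfg: PipelineConfig | None = None
) -> PipelineReport:
    """Convenience wrapper: generate the synthetic dataset, then run."""
    syn = syn or SyntheticConfig()
    cfg = cfg or PipelineConfig(seed=syn.seed)
    return run_pipeline(generate_dataset(syn), cfg)


def analyze_sentence(
    text_or_path: str | Path,
    alphabet_size: int = DLOB_ALPHABET_SIZE,
) -> XAIReport:
    """Symbolic statistics of a concatenated symbol sentence.

    Accepts either a path to a text file or the sentence string itself.
    ``alphabet_size`` is the utilized symbol count used as the complexity
    denominator.  Two-letter region sentences (starting with a lobe
    letter) and single-letter hemispheric sentences over ``{L, R, z}``
    are both supported; a hemispheric sentence is reported as its own
    symbol sequence.
    """
    from .dlob import (
        HEMISPHERES,
        DLobError,
        sequence_histogram,
        sequence_transition_matrix,
        shannon_entropy,
        complexity_ratio,
    )

    try:
        is_file = Path(text_or_path).is_file()
    except (OSError, ValueError):  # raw sentences can exceed path-length limits
        is_file = False
    text = (Path(text_or_path).read_text() if is_file else str(text_or_path)).strip()
    if not text:
        raise DLobError("empty sentence")
    if text[0] in "LRz":  # hemispheric: one character per symbol
        bad = [c for c in text if c not in HEMISPHERES]
        if bad:
            raise DLobError(f"invalid hemispheric symbols: {sorted(set(bad))}")
        seq = list(text)
        return XAIReport(
            symbol_sequence=seq,
            hemispheric=seq,
            symbol_histogram=sequence_histogram(seq, HEMISPHERES),
            hemispheric_histogram=sequence_histogram(seq, HEMISPHERES),
            symbol_transitions=sequence_transition_matrix(seq, HEMISPHERES),
            hemispheric_transitions=sequence_transition_matrix(seq, HEMISPHERES),
            symbol_entropy=shannon_entropy(seq),
            hemispheric_entropy=shannon_entropy(seq),
            symbol_complexity=complexity_ratio(seq, alphabet_size),
            hemispheric_complexity=complexity_ratio(seq, alphabet_size),
            symbol_alphabet=list(HEMISPHERES),
        )
    seq = tokenize_sentence(text)
    return analyze_sequence(seq, symbol_alphabet_size=alphabet_size)
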