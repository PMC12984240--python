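"""Self-organizing kNN ensemble with iterative majority voting.

A bag of kNN parameterizations (neighbor count x distance x vote
weighting; 120 combinations under the defaults) is swept with stratified
cross-validation, producing one out-of-fold prediction vector per
combination.  Outcomes are sorted by accuracy, per-sample majority votes
over the top-3, top-4, ..., top-NP outcomes add NP - 2 voted outcomes,
and the single best of all ``2*NP - 2`` outcomes is returned.  Note the
sorting and final selection consult the true labels of the pooled
cross-validated predictions, so the reported best accuracy is an
optimistic model-selection statistic, reproduced here by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

DELTA = 1e-12  # guards inverse-distance vote weights

DISTANCES = ("euclidean", "spearman", "cityblock", "cosine")
WEIGHTINGS = ("inverse", "squared-inverse", "equal")


class ClassifierError(ValueError):
    """Raised for invalid classifier parameters or inputs."""


@dataclass(frozen=True)
class ParameterBag:
    """The grid of kNN parameterizations swept by the ensemble."""

    k_values: tuple[int, ...] = tuple(range(1, 11))
    distances: tuple[str, ...] = DISTANCES
    weightings: tuple[str, ...] = WEIGHTINGS

    @property
    def combinations(self) -> list[tuple[int, str, str]]:
        # k fastest, then distance, then weighting: a stable, documented order
        return [
            (k, d, w)
            for w in self.weightings
            for d in self.distances
            for k in self.k_values
        ]

    @property
    def n_combinations(self) -> int:
        return len(self.k_values) * len(self.distances) * len(self.weightings)


@dataclass
class OutcomeSet:
    """All parametric and voted out-of-fold outcomes of one ensemble run."""

    parametric: np.ndarray  # (NP, Ns) predicted labels (encoded)
    parametric_acc: np.ndarray  # (NP,)
    voted: np.ndarray  # (NP - 2, Ns)
    voted_acc: np.ndarray  # (NP - 2,)
    final: np.ndarray  # (Ns,)
    final_acc: float
    final_index: int  # index into the concatenated outcome list
    classes: np.ndarray  # label values, sorted; predictions are indices into this

    @property
    def n_outcomes(self) -> int:
        return len(self.parametric_acc) + len(self.voted_acc)

    def final_labels(self) -> np.ndarray:
        return self.classes[self.final]

    def to_dict(self) -> dict:
        return {
            "n_parametric": len(self.parametric_acc),
            "n_voted": len(self.voted_acc),
            "n_outcomes": self.n_outcomes,
            "parametric_acc": self.parametric_acc.tolist(),
            "voted_acc": self.voted_acc.tolist(),
            "final_acc": self.final_acc,
            "final_index": int(self.final_index),
        }


@dataclass
class MetricReport:
    """Confusion-matrix performance summary (binary or macro-averaged)."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    geometric_mean: float
    confusion: np.ndarray
    degenerate: bool = False  # a zero-denominator ratio was reported as 0

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "geometric_mean": self.geometric_mean,
            "confusion": self.confusion.tolist(),
            "degenerate": self.degenerate,
        }


def _spearman_distance(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """1 - Spearman rank correlation between feature vectors.

    A constant vector has undefined rank correlation; that pair's
    correlation is defined as 0 (distance 1).
    """
    ra = np.apply_along_axis(rankdata, 1, A)
    rb = np.apply_along_axis(rankdata, 1, B)
    ra_c = ra - ra.mean(axis=1, keepdims=True)
    rb_c = rb - rb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ra_c, axis=1)
    nb = np.linalg.norm(rb_c, axis=1)
    num = ra_c @ rb_c.T
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return 1.0 - corr


def pairwise_distance(A: np.ndarray, B: np.ndarray, distance: str) -> np.ndarray:
    """Distance matrix between the rows of ``A`` (queries) and ``B`` (references)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if distance in ("euclidean", "cityblock", "cosine"):
        d = cdist(A, B, metric=distance)
        # cdist yields NaN for a zero-norm vector under cosine; treat as max distance
        if distance == "cosine":
            d = np.nan_to_num(d, nan=1.0)
        return d
    if distance == "spearman":
        return _spearman_distance(A, B)
    raise ClassifierError(f"unknown distance {distance!r}")


def _vote(
    dist: np.ndarray,
    train_y: np.ndarray,
    n_classes: int,
    k: int,
    weighting: str,
) -> np.ndarray:
    """Weighted kNN vote given a (queries x train) distance matrix.

    Distance ties break toward the earlier training index (stable sort);
    vote ties break toward the smallest class value.
    """
    if k > dist.shape[1]:
        raise ClassifierError(f"k={k} exceeds training-set size {dist.shape[1]}")
    nn = np.argsort(dist, axis=1, kind="stable")[:, :k]
    nd = np.take_along_axis(dist, nn, axis=1)
    if weighting == "equal":
        wts = np.ones_like(nd)
    elif weighting == "inverse":
        wts = 1.0 / (nd + DELTA)
    elif weighting == "squared-inverse":
        wts = 1.0 / (nd + DELTA) ** 2
    else:
        raise ClassifierError(f"unknown weighting {weighting!r}")
    votes = np.zeros((dist.shape[0], n_classes))
    labels_nn = train_y[nn]
    for c in range(n_classes):
        votes[:, c] = np.where(labels_nn == c, wts, 0.0).sum(axis=1)
    # argmax returns the first (smallest) class on ties
    return votes.argmax(axis=1)


def knn_predict(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    k: int,
    distance: str = "euclidean",
    weighting: str = "equal",
) -> np.ndarray:
    """Predict test labels with a single kNN parameterization.

    Supported distances: euclidean, cityblock, cosine, spearman (1 minus
    the rank correlation of the feature vectors).  Vote weightings:
    equal, inverse ``1/(d+delta)``, squared-inverse ``1/(d+delta)**2``.
    """
    train_y = np.asarray(train_y)
    classes, enc = np.unique(train_y, return_inverse=True)
    dist = pairwise_distance(test_X, train_X, distance)
    pred = _vote(dist, enc, len(classes), k, weighting)
    return classes[pred]


def crossval_outcomes(
    SX: np.ndarray,
    y: np.ndarray,
    bag: ParameterBag | None = None,
    folds: int = 10,
    seed: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Out-of-fold prediction vectors for every parameter combination.

    Returns ``(parametric, acc, classes)`` where ``parametric`` has shape
    ``(NP, Ns)`` holding encoded class indices and ``acc[i]`` is the
    pooled out-of-fold accuracy of combination ``i``.  Folding is
    stratified with a fixed shuffle seed so every class appears in every
    training split.
    """
    bag = bag or ParameterBag()
    SX = np.asarray(SX, dtype=float)
    y = np.asarray(y)
    classes, enc = np.unique(y, return_inverse=True)
    if folds < 2:
        raise ClassifierError("need at least 2 folds")
    combos = bag.combinations
    NP = len(combos)
    ns = len(y)
    preds = np.empty((NP, ns), dtype=np.int64)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(SX, enc):
        # one distance matrix per metric per fold, shared across k and weighting
        dists = {
            name: pairwise_distance(SX[te], SX[tr], name) for name in bag.distances
        }
        for i, (k, dname, wname) in enumerate(combos):
            preds[i, te] = _vote(dists[dname], enc[tr], len(classes), k, wname)
    acc = (preds == enc[None, :]).mean(axis=1)
    return preds, acc, classes


def iterative_majority_voting(
    sorted_outcomes: np.ndarray, y_enc: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mode over the top-3, top-4, ..., top-NP outcomes.

    ``sorted_outcomes`` must already be in descending-accuracy order.
    Mode ties break toward the smallest class value.  Returns the
    ``NP - 2`` voted outcome vectors and their accuracies.
    """
    NP, ns = np.asarray(sorted_outcomes).shape
    if NP < 3:
        raise ClassifierError("iterative majority voting needs at least 3 outcomes")
    n_classes = int(max(sorted_outcomes.max(), y_enc.max())) + 1
    voted = np.empty((NP - 2, ns), dtype=np.int64)
    counts = np.zeros((ns, n_classes), dtype=np.int64)
    idx = np.arange(ns)
    for i in range(NP):
        counts[idx, sorted_outcomes[i]] += 1
        if i >= 2:
            voted[i - 2] = counts.argmax(axis=1)  # first max = smallest class
    acc = (voted == y_enc[None, :]).mean(axis=1)
    return voted, acc


def greedy_final(
    accuracies: np.ndarray, outcomes: np.ndarray
) -> tuple[np.ndarray, float, int]:
    """The maximal-accuracy outcome; ties break toward the smaller index."""
    accuracies = np.asarray(accuracies, dtype=float)
    if accuracies.size == 0:
        raise ClassifierError("no outcomes to choose from")
    best = int(np.argmax(accuracies))
    return np.asarray(outcomes)[best], float(accuracies[best]), best


def run_tknn(
    SX: np.ndarray,
    y: np.ndarray,
    bag: ParameterBag | None = None,
    folds: int = 10,
    seed: int = 1,
) -> OutcomeSet:
    """Full ensemble: parametric sweep, iterative voting, greedy selection."""
    bag = bag or ParameterBag()
    y = np.asarray(y)
    classes = np.unique(y)
    enc = np.searchsorted(classes, y)
    preds, acc, classes = crossval_outcomes(SX, y, bag, folds=folds, seed=seed)
    # stable descending sort keeps the earlier combination on accuracy ties
    order = np.argsort(-acc, kind="stable")
    voted, vacc = iterative_majority_voting(preds[order], enc)
    all_outcomes = np.vstack([preds, voted])
    all_acc = np.concatenate([acc, vacc])
    final, final_acc, idx = greedy_final(all_acc, all_outcomes)
    return OutcomeSet(
        parametric=preds,
        parametric_acc=acc,
        voted=voted,
        voted_acc=vacc,
        final=final,
        final_acc=final_acc,
        final_index=idx,
        classes=classes,
    )


def confusion_metrics(
    y: np.ndarray, yhat: np.ndarray, positive_class=None
) -> MetricReport:
    """Accuracy, sensitivity, specificity, precision, F1 and geometric mean.

    Binary problems use ``positive_class`` (default: the larger label
    value); multiclass metrics are macro-averaged one-vs-rest.  A ratio
    with zero denominator is reported as 0 and flags the report as
    degenerate.
    """
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.size == 0 or y.shape != yhat.shape:
        raise ClassifierError("labels and predictions must be equal-length, non-empty")
    classes = np.unique(np.concatenate([y, yhat]))
    n = len(classes)
    cm = np.zeros((n, n), dtype=np.int64)
    yi = np.searchsorted(classes, y)
    pi = np.searchsorted(classes, yhat)
    np.add.at(cm, (yi, pi), 1)

    degenerate = False

    def ratio(num: float, den: float) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    if n == 2:
        if positive_class is None:
            positive_class = classes[-1]
        p = int(np.nonzero(classes == positive_class)[0][0])
        pos_sets = [p]
    else:
        pos_sets = list(range(n))

    sens, spec, prec, f1s = [], [], [], []
    for c in pos_sets:
        tp = cm[c, c]
        fn = cm[c].sum() - tp
        fp = cm[:, c].sum() - tp
        tn = cm.sum() - tp - fn - fp
        se = ratio(tp, tp + fn)
        sp = ratio(tn, tn + fp)
        pr = ratio(tp, tp + fp)
        f1 = ratio(2 * pr * se, pr + se)
        sens.append(se)
        spec.append(sp)
        prec.append(pr)
        f1s.append(f1)
    se, sp = float(np.mean(sens)), float(np.mean(spec))
    report = MetricReport(
        accuracy=float(np.trace(cm) / cm.sum()),
        sensitivity=se,
        specificity=sp,
        precision=float(np.mean(prec)),
        f1=float(np.mean(f1s)),
        geometric_mean=float(np.sqrt(se * sp)),
        confusion=cm,
        degenerate=degenerate,
    )
    if degenerate:
        warnings.warn("zero-denominator metric reported as 0", RuntimeWarning)
    return report
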