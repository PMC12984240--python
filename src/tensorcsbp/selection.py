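"""Cumulative-weighted NCA feature selection.

The selector (i) min-max normalizes every sample row into [0, 1), (ii)
learns one non-negative relevance weight per feature with a diagonal
neighborhood component analysis (NCA), (iii) orders features by
descending weight, and (iv) keeps the smallest prefix whose cumulative
weight mass reaches a threshold ``th`` of the total mass, so the number
of retained features is chosen by the weights themselves rather than
fixed a priori.

The NCA variant used here learns a per-feature scaling (not a full
linear map): with weights ``w`` the distance between samples is
``d_w(x_i, x_j) = sum_r w_r**2 |x_ir - x_jr|`` and the leave-one-out
probability that ``i`` picks ``j`` as its neighbor is
``p_ij = exp(-d_w(x_i, x_j)) / sum_{k != i} exp(-d_w(x_i, x_k))``.
The objective maximized is the expected number of correctly classified
samples minus an L2 penalty ``lambda * sum w_r**2``.  Optimization is
deterministic: all-ones initialization, L-BFGS with an analytic
gradient, fixed iteration cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

EPS_DEFAULT = 1e-12
DEFAULT_THRESHOLD = 0.9999


class SelectionError(ValueError):
    """Raised for degenerate selection inputs."""


@dataclass
class SelectionResult:
    """Outcome of cumulative-weighted NCA selection.

    Attributes
    ----------
    weights : ndarray, shape (F,)
        Non-negative per-feature NCA weights.
    order : ndarray, shape (F,)
        0-based feature indices by descending weight (ties toward the
        smaller index).
    n_selected : int
        Number of features kept by the cumulative-weight rule.
    selected_indices : ndarray, shape (n_selected,)
        The first ``n_selected`` entries of ``order`` (0-based).
    selected_matrix : ndarray, shape (Ns, n_selected)
        Columns of the row-normalized feature matrix at
        ``selected_indices``, in order.
    threshold : float
        The cumulative-mass threshold used.
    """

    weights: np.ndarray
    order: np.ndarray
    n_selected: int
    selected_indices: np.ndarray
    selected_matrix: np.ndarray
    threshold: float = DEFAULT_THRESHOLD

    @property
    def selected_indices_1based(self) -> np.ndarray:
        """Selected indices in the 1-based convention the symbolic decoder uses."""
        return self.selected_indices + 1

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_selected": int(self.n_selected),
            "selected_indices_1based": self.selected_indices_1based.tolist(),
            "weights": self.weights.tolist(),
        }


def rowwise_minmax_normalize(X: np.ndarray, eps: float = EPS_DEFAULT) -> np.ndarray:
    """Map each sample row to ``(x - min(x)) / (max(x) - min(x) + eps)``.

    Normalization is per row (per sample), not per feature column; a
    constant row maps to all zeros because ``eps`` guards the division.
    """
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    return (X - lo) / (hi - lo + eps)


def _nca_objective_grad(
    w: np.ndarray, delta: np.ndarray, same: np.ndarray, lam: float
) -> tuple[float, np.ndarray]:
    """Negative NCA objective and its gradient in the raw parameters ``w``.

    ``delta[i, j, r] = |x_ir - x_jr|``; ``same[i, j]`` marks same-class
    pairs (diagonal False).
    """
    d = delta @ (w * w)  # (N, N) weighted distances
    np.fill_diagonal(d, np.inf)  # exclude self-neighbors
    d -= d.min(axis=1, keepdims=True)  # stabilize the softmax
    ex = np.exp(-d)
    ex_sum = ex.sum(axis=1, keepdims=True)
    P = ex / ex_sum
    p_correct = (P * same).sum(axis=1)  # p_i
    obj = p_correct.sum() - lam * np.dot(w, w)
    # dp_i/dw_r = 2 w_r [ p_i sum_j P_ij delta_ijr - sum_{j same} P_ij delta_ijr ]
    M = P * (p_correct[:, None] - same)
    grad = 2.0 * w * np.einsum("ij,ijr->r", M, delta) - 2.0 * lam * w
    return -obj, -grad


def nca_weights(
    X: np.ndarray,
    y: np.ndarray,
    lam: float | None = None,
    max_iter: int = 100,
) -> np.ndarray:
    """Non-negative per-feature NCA relevance weights.

    Weights are the squares of the optimized parameters, so they are
    non-negative by construction.  ``lam`` defaults to ``1 / Ns``.  With
    ``max_iter=0`` the all-ones initialization is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, F = X.shape
    if n < 2:
        raise SelectionError("need at least two samples")
    if len(np.unique(y)) < 2:
        raise SelectionError("need at least two classes for NCA weighting")
    if lam is None:
        lam = 1.0 / n
    w0 = np.ones(F)
    if max_iter == 0:
        return w0 * w0
    delta = np.abs(X[:, None, :] - X[None, :, :])
    same = (y[:, None] == y[None, :]).astype(float)
    np.fill_diagonal(same, 0.0)
    res = minimize(
        _nca_objective_grad,
        w0,
        args=(delta, same, lam),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    w = res.x
    return w * w


def cumulative_weight_count(weights: np.ndarray, order: np.ndarray, th: float) -> int:
    """Smallest m whose top-m weight mass reaches ``th`` of the total mass."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()
    if total <= 0:
        raise SelectionError("all-zero weights: cumulative rule undefined")
    if not 0 < th <= 1:
        raise SelectionError(f"threshold must be in (0, 1], got {th}")
    csum = np.cumsum(weights[order])
    hit = np.nonzero(csum >= th * total)[0]
    return int(hit[0]) + 1 if hit.size else len(weights)


def select_features(
    X: np.ndarray,
    y: np.ndarray,
    th: float = DEFAULT_THRESHOLD,
    eps: float = EPS_DEFAULT,
    lam: float | None = None,
    max_iter: int = 100,
) -> SelectionResult:
    """Full cumulative-weighted NCA selection on a raw feature matrix.

    Rows of ``X`` are min-max normalized, NCA weights are learned on the
    normalized matrix, and the smallest descending-weight prefix reaching
    ``th`` of the total weight mass is kept.  ``selected_indices`` refer
    to the original column positions of ``X``.
    """
    X = np.asarray(X, dtype=float)
    Xn = rowwise_minmax_normalize(X, eps=eps)
    if X.shape[1] == 1:
        # single feature: nothing to weight, it is always kept
        return SelectionResult(
            weights=np.ones(1),
            order=np.zeros(1, dtype=int),
            n_selected=1,
            selected_indices=np.zeros(1, dtype=int),
            selected_matrix=Xn,
            threshold=th,
        )
    wt = nca_weights(Xn, y, lam=lam, max_iter=max_iter)
    order = np.argsort(-wt, kind="stable")
    of = cumulative_weight_count(wt, order, th)
    sel = order[:of]
    return SelectionResult(
        weights=wt,
        order=order,
        n_selected=of,
        selected_indices=sel,
        selected_matrix=Xn[:, sel],
        threshold=th,
    )
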