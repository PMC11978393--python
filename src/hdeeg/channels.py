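"""Channel-importance analyses: lasso selection and degree centrality.

Important channels are found by regressing a pre/post-stimulus indicator
(0 before, 1 after) on the standardized channel signals with an l1 penalty,

    beta_hat = argmin_beta (1/n) ||Y - X beta||^2 + lambda ||beta||_1,

and reading off the channels with nonzero coefficients.  Selections from
many individual recordings are aggregated into per-channel selection
frequencies.  Dominant channels of a significant-change network are ranked
by degree centrality (incident-edge counts).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelSelection",
    "CentralityReport",
    "lasso_select",
    "selection_frequency",
    "degree_centrality",
]


@dataclass
class ChannelSelection:
    """Lasso fit summary: standardized coefficients and the selected set."""

    coefficients: np.ndarray
    selected: list[int]
    lambda_used: float


@dataclass
class CentralityReport:
    degrees: np.ndarray
    top_k: list[str]


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center and unit-scale; returns (standardized, sd) with
    constant columns left centered only."""
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    return M / safe, sd


def lasso_select(
    X: np.ndarray,
    Y: np.ndarray,
    lam: Union[float, str] = "cv",
    n_folds: int = 10,
    seed: int = 0,
    loss: str = "squared",
) -> ChannelSelection:
    """Select channels explaining the pre/post indicator with an l1 penalty.

    Parameters
    ----------
    X
        (observations x channels) matrix.
    Y
        Binary indicator (0 pre-stimulus, 1 post-stimulus); both classes
        must be present.
    lam
        Penalty weight on the (1/n)||.||^2 scale, or ``"cv"`` to pick it by
        K-fold cross-validation (minimum mean error rule, seeded folds).
        ``lam=0`` with p < n returns the least-squares solution.
    loss
        ``"squared"`` for the l1-penalized squared-error fit (the primary
        definition), ``"logistic"`` for an l1 logistic variant.

    Notes
    -----
    Coefficients are reported on the standardized scale.  The squared-error
    path runs through scikit-learn's coordinate descent, whose objective
    ``(1/2n)||Y - Xb||^2 + alpha ||b||_1`` matches the (1/n) scaling at
    ``alpha = lam / 2``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape[0] != Y.size:
        raise ValueError("X rows must match Y length")
    classes = np.unique(Y)
    if classes.size < 2:
        raise ValueError("Y must contain both classes (0 and 1)")
    Xs, sd = _standardize(X)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant channel(s) dropped from selection", int(constant.sum())
        )
    Ys, _ = _standardize(Y[:, None])
    Ys = Ys.ravel()

    if loss == "logistic":
        C = 1.0 if lam == "cv" else 1.0 / max(float(lam), 1e-12)
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="liblinear", random_state=seed
        ).fit(Xs, (Y > classes.mean()).astype(int))
        coef = model.coef_.ravel()
        lam_used = 1.0 / C
    elif lam == "cv":
        cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        model = LassoCV(cv=cv, random_state=seed).fit(Xs, Ys)
        coef = model.coef_
        lam_used = 2.0 * float(model.alpha_)
    else:
        lam = float(lam)
        if lam < 0:
            raise ValueError("lambda must be nonnegative")
        if lam == 0:
            coef, *_ = np.linalg.lstsq(Xs, Ys, rcond=None)
            lam_used = 0.0
        else:
            model = Lasso(alpha=lam / 2.0, max_iter=50_000, tol=1e-10).fit(Xs, Ys)
            coef = model.coef_
            lam_used = lam
    coef = np.asarray(coef, dtype=float)
    coef[constant] = 0.0
    selected = [int(i) for i in np.nonzero(coef)[0]]
    return ChannelSelection(coefficients=coef, selected=selected, lambda_used=lam_used)


def selection_frequency(
    selections: Sequence[ChannelSelection],
    labels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-channel counts of how many fits selected each channel."""
    if len(selections) == 0:
        raise ValueError("no selections supplied")
    p = selections[0].coefficients.size
    for s in selections:
        if s.coefficients.size != p:
            raise ValueError("selections have inconsistent channel counts")
    if labels is None:
        labels = [f"ch{i}" for i in range(p)]
    if len(labels) != p:
        raise ValueError("labels length mismatch")
    counts = np.zeros(p, dtype=int)
    for s in selections:
        counts[s.selected] += 1
    return (
        pd.DataFrame({"channel": list(labels), "count": counts})
        .sort_values(["count", "channel"], ascending=[False, True])
        .reset_index(drop=True)
    )


def degree_centrality(
    edges: Sequence[tuple[int, int]],
    p: int,
    labels: Optional[Sequence[str]] = None,
    k: int = 5,
) -> CentralityReport:
    """Degree per channel and the top-k ranking of an undirected edge list.

    Ties in degree break by label order, so reports are deterministic.
    """
    if labels is None:
        labels = [f"ch{i}" for i in range(p)]
    if len(labels) != p:
        raise ValueError("labels length mismatch")
    degrees = np.zeros(p, dtype=int)
    for i, j in edges:
        if not (0 <= i < p and 0 <= j < p):
            raise ValueError(f"edge ({i},{j}) out of range for p={p}")
        degrees[i] += 1
        degrees[j] += 1
    order = sorted(range(p), key=lambda i: (-degrees[i], labels[i]))
    return CentralityReport(degrees=degrees, top_k=[labels[i] for i in order[:k]])
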