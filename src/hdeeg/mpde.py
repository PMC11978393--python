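"""De-biased multi-population entrywise precision-matrix inference (MPDe).

Penalized precision estimates are biased, which invalidates naive entrywise
inference.  The de-biasing correction

    Theta_tilde = 2 Theta_hat - Theta_hat S Theta_hat

removes the first-order penalization bias, after which a linear combination
of de-biased entries across G populations,

    T_ij = sum_g a_g Theta_tilde_g;ij,

is asymptotically normal under the null
``sum_g a_g Theta0_g;ij = Theta0_ij``:

    sqrt(n) (T_ij - Theta0_ij) / sigma_hat_ij  ->  N(0, 1),

with the consistent variance estimator
``sigma_hat_ij^2 = sum_g a_g^2 (Theta_tilde_g;ii Theta_tilde_g;jj
+ Theta_tilde_g;ij^2)``.  The two-sample equality test of pre- vs
post-stimulus precision matrices is the special case a = (1, -1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "DebiasedSet",
    "MpdeResult",
    "debias",
    "mpde_test",
    "significant_network",
]


@dataclass
class DebiasedSet:
    """G de-biased precision matrices with their sample sizes."""

    Theta_tilde: list[np.ndarray]
    sample_sizes: list[int]

    def __post_init__(self) -> None:
        self.Theta_tilde = [np.asarray(T, dtype=float) for T in self.Theta_tilde]
        p = self.Theta_tilde[0].shape[0]
        for i, T in enumerate(self.Theta_tilde):
            if T.shape != (p, p):
                raise ValueError(f"matrix {i} has shape {T.shape}")
        if len(self.sample_sizes) != len(self.Theta_tilde):
            raise ValueError("sample_sizes length mismatch")

    @property
    def p(self) -> int:
        return self.Theta_tilde[0].shape[0]

    @property
    def G(self) -> int:
        return len(self.Theta_tilde)


@dataclass
class MpdeResult:
    """Entrywise test statistics, p-values and the retained edge set."""

    coefficients: np.ndarray
    stat: np.ndarray
    pvalues: np.ndarray
    edges: list[tuple[int, int]] = field(default_factory=list)
    threshold: float = 0.01


def debias(Theta_hat: np.ndarray, S: np.ndarray) -> np.ndarray:
    """First-order bias correction ``2 Theta_hat - Theta_hat S Theta_hat``.

    Exact-inverse fixed point: if ``Theta_hat = S^{-1}`` the correction
    returns ``S^{-1}`` unchanged.
    """
    Theta_hat = np.asarray(Theta_hat, dtype=float)
    S = np.asarray(S, dtype=float)
    if Theta_hat.shape != S.shape or Theta_hat.ndim != 2:
        raise ValueError("shape mismatch between Theta_hat and S")
    out = 2.0 * Theta_hat - Theta_hat @ S @ Theta_hat
    return 0.5 * (out + out.T)


def mpde_test(
    debiased: DebiasedSet,
    a: Sequence[float],
    null_value: Optional[np.ndarray] = None,
    n_eff: Optional[int] = None,
    threshold: float = 0.01,
    bh_correct: bool = False,
) -> MpdeResult:
    """Entrywise z-test of the linear combination sum_g a_g Theta_g;ij.

    Parameters
    ----------
    debiased
        De-biased matrices and group sample sizes.
    a
        Combination coefficients of length G (e.g. ``(1, -1)`` for a
        two-sample equality test).
    null_value
        Hypothesized p x p matrix of combination values (default zero).
    n_eff
        Sample size used in the sqrt(n) scaling.  Defaults to ``min_g n_g``;
        a warning is logged when group sizes differ.
    threshold
        Per-entry p-value cutoff for edge retention (default 0.01).
    bh_correct
        Apply a Benjamini-Hochberg correction over the upper triangle before
        thresholding (off by default).
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (debiased.G,):
        raise ValueError(f"coefficient vector length {a.size} != G={debiased.G}")
    p = debiased.p
    if null_value is None:
        null_value = np.zeros((p, p))
    null_value = np.asarray(null_value, dtype=float)
    if n_eff is None:
        sizes = set(debiased.sample_sizes)
        if len(sizes) > 1:
            logger.warning(
                "unequal group sizes %s: using n_eff=min(n_g)=%d for the "
                "sqrt(n) scaling",
                debiased.sample_sizes,
                min(sizes),
            )
        n_eff = min(debiased.sample_sizes)
    if n_eff <= 0:
        raise ValueError("n_eff must be positive")

    T = sum(ag * Tg for ag, Tg in zip(a, debiased.Theta_tilde))
    var = np.zeros((p, p))
    for ag, Tg in zip(a, debiased.Theta_tilde):
        var += ag**2 * (np.outer(np.diag(Tg), np.diag(Tg)) + Tg**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.sqrt(float(n_eff)) * (T - null_value) / np.sqrt(var)
    degenerate = var <= 0
    if degenerate.any():
        logger.warning(
            "%d entries have zero estimated variance; statistics set to NaN",
            int(degenerate.sum()),
        )
        stat[degenerate] = np.nan
    stat = 0.5 * (stat + stat.T)
    pvals = 2.0 * stats.norm.sf(np.abs(stat))
    pvals = np.where(np.isnan(stat), np.nan, pvals)

    iu, ju = np.triu_indices(p, k=1)
    upper = pvals[iu, ju]
    if bh_correct:
        finite = np.isfinite(upper)
        cut = np.full(upper.shape, False)
        if finite.any():
            pv = upper[finite]
            order = np.argsort(pv)
            m = pv.size
            ok = pv[order] <= threshold * np.arange(1, m + 1) / m
            sel = np.zeros(m, dtype=bool)
            if ok.any():
                sel[order[: np.max(np.nonzero(ok)[0]) + 1]] = True
            cut[finite] = sel
    else:
        cut = upper < threshold
    edges = [(int(i), int(j)) for i, j, c in zip(iu, ju, cut) if c]
    return MpdeResult(
        coefficients=a,
        stat=stat,
        pvalues=pvals,
        edges=edges,
        threshold=threshold,
    )


def significant_network(
    result: MpdeResult, labels: Sequence[str]
) -> list[tuple[str, str]]:
    """Labeled undirected edge list of the significantly changed pairs."""
    p = result.stat.shape[0]
    if len(labels) != p:
        raise ValueError(f"labels length {len(labels)} != p={p}")
    return [(labels[i], labels[j]) for i, j in result.edges]
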