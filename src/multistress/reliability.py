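"""Measurement reliability, validity and fit metrics for reflective blocks.

All functions operate on plain loadings/weights/correlation inputs so they
can be exercised independently of a fitted model:

* AVE — convergent validity, mean squared loading.
* Cronbach's alpha (standardized), rho_A (Dijkstra-Henseler) and rho_C
  (composite reliability) — internal consistency.
* HTMT — discriminant validity (heterotrait-monotrait correlation ratio).
* SRMR — global fit versus a model-implied correlation matrix.
* f2 and VIF — structural effect size and collinearity diagnostics.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "ave",
    "cronbach_alpha",
    "rho_c",
    "rho_a",
    "htmt",
    "srmr",
    "f_squared",
    "classify_f2",
    "vif_from_r2",
]


def ave(loadings) -> float:
    """Average variance extracted: mean of squared loadings."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("need at least one loading")
    return float(np.mean(lam**2))


def cronbach_alpha(corr) -> float:
    """Standardized Cronbach's alpha, K r / (1 + (K-1) r), with r the mean
    off-diagonal correlation of the block.  Single-indicator blocks are 1
    by convention (flagged with a warning)."""
    S = np.atleast_2d(np.asarray(corr, dtype=float))
    k = S.shape[0]
    if k == 1:
        warnings.warn("single-indicator block: alpha reported as 1 by convention")
        return 1.0
    off = S[~np.eye(k, dtype=bool)]
    rbar = float(off.mean())
    return k * rbar / (1.0 + (k - 1) * rbar)


def rho_c(loadings) -> float:
    """Composite reliability: (sum lam)^2 / ((sum lam)^2 + sum(1 - lam^2))."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("need at least one loading")
    num = float(lam.sum()) ** 2
    denom = num + float(np.sum(1.0 - lam**2))
    return num / denom if denom > 0 else 0.0


def rho_a(weights, corr) -> float:
    """Dijkstra-Henseler rho_A from outer weights and the block correlation
    matrix:

        (w'w)^2 * w'(S - diag S)w / w'(ww' - diag(ww'))w
    """
    w = np.asarray(weights, dtype=float)
    S = np.atleast_2d(np.asarray(corr, dtype=float))
    k = w.size
    if k == 1:
        warnings.warn("single-indicator block: rho_A reported as 1 by convention")
        return 1.0
    var = float(w @ S @ w)
    if var <= 0:
        raise ValueError("rho_A undefined: weights give a zero-variance composite")
    w = w / np.sqrt(var)  # unit-variance composite normalization
    S_off = S - np.diag(np.diag(S))
    ww = np.outer(w, w)
    ww_off = ww - np.diag(np.diag(ww))
    denom = float(w @ ww_off @ w)
    if abs(denom) < 1e-14:
        raise ValueError("rho_A undefined: degenerate off-diagonal weight structure")
    num = float(w @ S_off @ w)
    return float(w @ w) ** 2 * num / denom


def htmt(indicator_corr: np.ndarray, block_a: list[int], block_b: list[int]) -> float:
    """Heterotrait-monotrait ratio for two blocks given the full indicator
    correlation matrix and the column indices of each block.

    Mean absolute heterotrait correlation divided by the geometric mean of
    the two mean monotrait correlations.  A single-indicator block
    contributes 1 to the geometric mean (its score is its indicator),
    which reduces HTMT to the plain indicator correlation when both blocks
    are singletons.
    """
    R = np.asarray(indicator_corr, dtype=float)
    hetero = float(np.mean(np.abs(R[np.ix_(block_a, block_b)])))

    def mono(block: list[int]) -> float:
        k = len(block)
        if k < 2:
            return 1.0
        sub = R[np.ix_(block, block)]
        return float(sub[~np.eye(k, dtype=bool)].mean())

    ma, mb = mono(block_a), mono(block_b)
    if ma <= 0 or mb <= 0:
        raise ValueError(
            f"non-positive monotrait mean (block means {ma:.4f}, {mb:.4f}); HTMT undefined"
        )
    return hetero / float(np.sqrt(ma * mb))


def srmr(empirical: np.ndarray, implied: np.ndarray) -> float:
    """Standardized root mean squared residual over the strictly-lower
    triangle of the two correlation matrices."""
    E = np.asarray(empirical, dtype=float)
    M = np.asarray(implied, dtype=float)
    if E.shape != M.shape or E.shape[0] != E.shape[1]:
        raise ValueError(f"dimension mismatch: {E.shape} vs {M.shape}")
    tri = np.tril_indices(E.shape[0], k=-1)
    resid = E[tri] - M[tri]
    return float(np.sqrt(np.mean(resid**2)))


def f_squared(r2_included: float, r2_excluded: float) -> float:
    """Effect size of one predictor: (R2_incl - R2_excl) / (1 - R2_incl)."""
    if r2_included >= 1.0:
        raise ValueError("R2 of the included model must be < 1")
    if not 0.0 <= r2_excluded <= r2_included + 1e-12:
        raise ValueError("require 0 <= r2_excluded <= r2_included")
    return max(0.0, (r2_included - r2_excluded) / (1.0 - r2_included))


def classify_f2(f2: float) -> str:
    """f2 bands: < 0.02 negligible, 0.02-0.15 weak, 0.15-0.35 moderate,
    > 0.35 large."""
    if f2 < 0:
        raise ValueError("f2 must be non-negative")
    if f2 < 0.02:
        return "negligible"
    if f2 < 0.15:
        return "weak"
    if f2 < 0.35:
        return "moderate"
    return "large"


def vif_from_r2(r2: float) -> float:
    """Variance inflation factor 1/(1-R2); infinite under perfect collinearity."""
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return 1.0 / (1.0 - r2)
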