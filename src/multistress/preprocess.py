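"""Pre-modeling transformations: Box-Cox, EM imputation, standardization.

Box-Cox power transforms are fitted per column by profile maximum
likelihood.  Missing cells are completed by a single EM imputation under a
multivariate normal model (conditional means, with conditional covariances
accumulated in the M-step), matching a missing-completely-at-random
photometry dropout.  Standardization is the usual z-score with the n-1
denominator, applied before any PLS estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "BoxCoxFit",
    "ImputationResult",
    "boxcox_transform",
    "boxcox_mle",
    "em_impute",
    "standardize",
]


@dataclass(frozen=True)
class BoxCoxFit:
    """Fitted Box-Cox exponent for one column."""

    lam: float
    loglik: float
    column: str = ""


@dataclass
class ImputationResult:
    """Completed table and the fitted multivariate-normal parameters."""

    completed: pd.DataFrame
    mu: pd.Series
    sigma: pd.DataFrame
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    imputed_cells: list[tuple[int, str]] = field(default_factory=list)


def boxcox_transform(x, lam: float) -> np.ndarray:
    """Box-Cox transform: (x**lam - 1)/lam, or log(x) at lam = 0."""
    x = np.asarray(x, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(f"Box-Cox requires positive values; offending rows: {bad.tolist()}")
    if lam == 0.0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def boxcox_mle(x, column: str = "", grid: int = 61) -> BoxCoxFit:
    """Profile-likelihood estimate of the Box-Cox exponent.

    The profile log-likelihood is evaluated on a grid over [-3, 3] and the
    best grid point is refined by bounded scalar minimization to an
    absolute tolerance of 1e-4.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError(f"need at least 5 observations, got {x.size}")
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(f"Box-Cox requires positive values; offending rows: {bad.tolist()}")
    if np.ptp(x) == 0:
        raise ValueError("constant column: Box-Cox likelihood is flat")

    lams = np.linspace(-3.0, 3.0, grid)
    llf = np.array([stats.boxcox_llf(l, x) for l in lams])
    k = int(np.argmax(llf))
    lo = lams[max(k - 1, 0)]
    hi = lams[min(k + 1, grid - 1)]
    res = optimize.minimize_scalar(
        lambda l: -stats.boxcox_llf(l, x),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-4},
    )
    lam, ll = float(res.x), float(-res.fun)
    if ll < llf[k]:  # refinement must not fall below the best grid point
        lam, ll = float(lams[k]), float(llf[k])
    return BoxCoxFit(lam=lam, loglik=ll, column=column)


def _observed_loglik(X: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    total = 0.0
    for row in X:
        o = ~np.isnan(row)
        if not o.any():
            continue
        total += stats.multivariate_normal.logpdf(
            row[o], mean=mu[o], cov=sigma[np.ix_(o, o)], allow_singular=True
        )
    return float(total)


def em_impute(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> ImputationResult:
    """Single EM imputation under a joint multivariate normal model.

    ``columns`` names the columns allowed to carry missing cells (all
    numeric columns by default); every other numeric column enters the
    model as a complete auxiliary variable, so all multinormal information
    is used.  The E-step replaces missing entries with conditional means
    and accumulates the conditional covariances; the M-step updates the
    mean vector and (ML, denominator n) covariance.  Iteration stops when
    the largest parameter change drops below ``tol``.  Observed cells are
    returned bit-exactly unchanged; the observed-data log-likelihood is
    checked to be non-decreasing at every step.
    """
    numeric = [c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])]
    if columns is None:
        columns = [c for c in numeric if table[c].isna().any()]
    for c in columns:
        if c not in numeric:
            raise ValueError(f"column {c!r} is not numeric")
        n_obs = int(table[c].notna().sum())
        if n_obs == 0:
            raise ValueError(f"column {c!r} is entirely missing")
        if n_obs < 3:
            raise ValueError(f"column {c!r} has fewer than 3 observed values")
    stray = [c for c in numeric if c not in columns and table[c].isna().any()]
    if stray:
        raise ValueError(f"missing cells outside the named columns: {stray}")

    X = table[numeric].to_numpy(dtype=float)
    n, p = X.shape
    miss = np.isnan(X)
    imputed_cells = [(int(i), numeric[j]) for i, j in zip(*np.nonzero(miss))]

    # initialize from mean-filled data
    mu = np.nanmean(X, axis=0)
    Xf = np.where(miss, mu, X)
    sigma = np.cov(Xf, rowvar=False, ddof=0)
    sigma = np.atleast_2d(sigma) + 1e-10 * np.eye(p)

    loglik_trace = [_observed_loglik(X, mu, sigma)]
    converged = False
    n_iter = 0
    Xhat = Xf
    for n_iter in range(1, max_iter + 1):
        Xhat = np.where(miss, 0.0, X)
        extra = np.zeros((p, p))  # sum of conditional covariances
        for i in range(n):
            m = miss[i]
            if not m.any():
                continue
            o = ~m
            Soo = sigma[np.ix_(o, o)]
            Smo = sigma[np.ix_(m, o)]
            solve = np.linalg.solve(Soo, (X[i, o] - mu[o]))
            Xhat[i, m] = mu[m] + Smo @ solve
            extra[np.ix_(m, m)] += sigma[np.ix_(m, m)] - Smo @ np.linalg.solve(Soo, Smo.T)
        mu_new = Xhat.mean(axis=0)
        centered = Xhat - mu_new
        sigma_new = (centered.T @ centered + extra) / n
        sigma_new = (sigma_new + sigma_new.T) / 2 + 1e-12 * np.eye(p)

        ll = _observed_loglik(X, mu_new, sigma_new)
        if ll < loglik_trace[-1] - 1e-8 * max(1.0, abs(loglik_trace[-1])):
            raise RuntimeError(
                f"EM observed-data log-likelihood decreased at iteration {n_iter}: "
                f"{loglik_trace[-1]:.8f} -> {ll:.8f}"
            )
        loglik_trace.append(ll)

        delta = max(np.max(np.abs(mu_new - mu)), np.max(np.abs(sigma_new - sigma)))
        mu, sigma = mu_new, sigma_new
        if delta < tol:
            converged = True
            break
    if not converged:
        import warnings

        warnings.warn(f"EM did not converge within {max_iter} iterations", RuntimeWarning)

    completed = table.copy()
    for i, j in zip(*np.nonzero(miss)):
        completed.loc[completed.index[i], numeric[j]] = Xhat[i, j]
    return ImputationResult(
        completed=completed,
        mu=pd.Series(mu, index=numeric),
        sigma=pd.DataFrame(sigma, index=numeric, columns=numeric),
        n_iter=n_iter,
        converged=converged,
        loglik_trace=loglik_trace,
        imputed_cells=imputed_cells,
    )


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Z-score every column (mean 0, sd 1, n-1 denominator)."""
    if table.isna().any().any():
        raise ValueError("standardize requires a complete table; impute first")
    sd = table.std(ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance columns: {dead}")
    return (table - table.mean()) / sd
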