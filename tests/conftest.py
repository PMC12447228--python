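"""Shared fixtures and independent oracles.

The oracles here deliberately use a different computational route from the
package (closed-form matrix algebra instead of sequential recursions) so
they can serve as cross-checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from multistress.model_spec import SemModel


def random_dag_model(rng: np.random.Generator, max_nodes: int = 5,
                     edge_prob: float = 0.5) -> tuple[SemModel, dict]:
    """Random single-indicator DAG with standardized coefficients scaled
    so every endogenous construct keeps positive residual variance."""
    k = int(rng.integers(2, max_nodes + 1))
    names = [f"c{i}" for i in range(k)]
    paths = []
    parents: dict[int, list[int]] = {}
    for j in range(1, k):
        pa = [i for i in range(j) if rng.random() < edge_prob]
        if not pa and rng.random() < 0.7:
            pa = [int(rng.integers(0, j))]
        parents[j] = pa
        paths += [(names[i], names[j]) for i in pa]
    model = SemModel(blocks={nm: [f"x{i}"] for i, nm in enumerate(names)},
                     paths=tuple(paths))
    # draw betas, rescaling per construct so the explained variance stays < 0.8
    S = np.eye(k)
    values: dict[tuple[str, str], float] = {}
    for j in range(1, k):
        pa = parents.get(j, [])
        if not pa:
            continue
        b = rng.normal(0, 0.5, len(pa))
        expl = float(b @ S[np.ix_(pa, pa)] @ b)
        if expl > 0.8:
            b *= np.sqrt(0.8 / expl)
        if np.max(np.abs(b)) > 0.95:
            b *= 0.95 / np.max(np.abs(b))
        for i in range(k):
            if i != j:
                S[j, i] = S[i, j] = float(b @ S[pa, i])
        S[j, j] = 1.0
        for i, bi in zip(pa, b):
            values[(names[i], names[j])] = float(bi)
    return model, values


def oracle_construct_cov(model: SemModel, values: dict, phi: np.ndarray | None = None):
    """Construct correlation matrix by solving the full linear system:
    Sigma = (I-B)^-1 Psi (I-B)^-T, with the endogenous residual variances
    obtained from the unit-diagonal condition as a linear solve."""
    names = model.constructs
    idx = {c: i for i, c in enumerate(names)}
    k = len(names)
    B = np.zeros((k, k))
    for (s, t), b in values.items():
        B[idx[t], idx[s]] = b
    A = np.linalg.inv(np.eye(k) - B)
    exo = [idx[c] for c in model.exogenous]
    endo = [i for i in range(k) if i not in exo]
    psi = np.zeros(k)
    phi = np.eye(len(exo)) if phi is None else phi
    Psi_exo = np.zeros((k, k))
    Psi_exo[np.ix_(exo, exo)] = phi
    base = A @ Psi_exo @ A.T
    if endo:
        M = (A**2)[np.ix_(endo, endo)]
        rhs = 1.0 - np.diag(base)[endo]
        psi[endo] = np.linalg.solve(M, rhs)
    Sigma = base + A @ np.diag(psi) @ A.T
    return pd.DataFrame(Sigma, index=names, columns=names)


def oracle_total_effects(model: SemModel, values: dict) -> np.ndarray:
    """Total-effect matrix (direct + all indirect) via (I-B)^-1 - I."""
    names = model.constructs
    idx = {c: i for i, c in enumerate(names)}
    k = len(names)
    B = np.zeros((k, k))
    for (s, t), b in values.items():
        B[idx[t], idx[s]] = b
    return np.linalg.inv(np.eye(k) - B) - np.eye(k)


def sequential_ols_paths(data: pd.DataFrame, model: SemModel) -> dict:
    """Standardized sequential OLS: the path-analysis solution a
    single-indicator PLS model must reproduce."""
    Z = (data - data.mean()) / data.std(ddof=1)
    out = {}
    for c in model.endogenous:
        preds = model.predecessors(c)
        cols = [model.blocks[p][0] for p in preds]
        y = Z[model.blocks[c][0]].to_numpy()
        X = Z[cols].to_numpy()
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        for p, b in zip(preds, coef):
            out[(p, c)] = float(b)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_model():
    """pahs -> pigments -> psii plus the direct pahs -> psii edge."""
    return SemModel(
        blocks={"pahs": ["a"], "pigments": ["b"], "psii": ["c"]},
        paths=(("pahs", "pigments"), ("pigments", "psii"), ("pahs", "psii")),
    )
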