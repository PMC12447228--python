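"""Partial least squares path modeling (PLS-SEM).

The estimator follows the classic alternating scheme for reflective
(Mode A) measurement models:

1. construct scores = standardized weighted sums of their indicators;
2. inner proxies by the *path* weighting scheme — predecessors of a
   construct are weighted by their joint multiple-regression coefficients
   onto the focal score, successors by their correlations (centroid and
   factor schemes available behind a flag);
3. Mode A outer weights = correlations of each indicator with the inner
   proxy of its construct;

iterated to convergence of the outer weights.  Loadings are
indicator-score correlations; structural coefficients are ordinary least
squares of each endogenous score on its predecessors' scores.  Sign
indeterminacy is resolved by forcing the dominant loading of every block
to be positive.

The public surface is statsmodels-like: :class:`PLSPathModel` holds data
plus a :class:`~multistress.model_spec.SemModel`; ``fit()`` returns a
:class:`PLSPathResults` that carries estimates, reliability/validity/fit
diagnostics and a ``summary()`` table, with bootstrap inference and
mediation analysis as results methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import reliability as rel
from .model_spec import SemModel

__all__ = [
    "PLSPathModel",
    "PLSPathResults",
    "BootstrapInference",
    "MediationResult",
    "enumerate_indirect",
    "prune_indicators",
    "PLSConvergenceError",
]


class PLSConvergenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Numeric core (plain arrays; called tens of thousands of times by the
# bootstrap, so no pandas in here)
# ---------------------------------------------------------------------------


class _Core:
    """Precompiled structure of a SemModel for fast repeated fitting."""

    def __init__(self, model: SemModel):
        self.model = model
        self.constructs = model.constructs
        self.cindex = {c: i for i, c in enumerate(self.constructs)}
        inds = model.indicators
        self.indicators = inds
        self.iindex = {x: i for i, x in enumerate(inds)}
        self.blocks = [
            np.array([self.iindex[x] for x in model.blocks[c]]) for c in self.constructs
        ]
        self.preds = [
            np.array([self.cindex[p] for p in model.predecessors(c)], dtype=int)
            for c in self.constructs
        ]
        self.succs = [
            np.array([self.cindex[s] for s in model.successors(c)], dtype=int)
            for c in self.constructs
        ]
        self.edges = list(model.paths)

    def fit(self, X: np.ndarray, scheme: str = "path", tol: float = 1e-7,
            max_iter: int = 300):
        """Run the PLS iteration on standardized data ``X`` (n x p).

        Returns (weights list, scores n x k, loadings list, betas dict,
        r2 dict-by-index, n_iter).
        """
        n, _ = X.shape
        k = len(self.constructs)
        W = [np.full(len(b), 1.0 / len(b)) for b in self.blocks]
        Y = np.empty((n, k))

        def _scores():
            for j, b in enumerate(self.blocks):
                y = X[:, b] @ W[j]
                sd = y.std(ddof=1)
                if sd <= 0:
                    raise ZeroDivisionError(f"zero-variance score for {self.constructs[j]!r}")
                Y[:, j] = y / sd

        _scores()
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            C = (Y.T @ Y) / (n - 1)  # score correlations
            Z = np.empty_like(Y)
            for j in range(k):
                pr, su = self.preds[j], self.succs[j]
                if pr.size == 0 and su.size == 0:
                    Z[:, j] = Y[:, j]
                    continue
                z = np.zeros(n)
                if pr.size:
                    if scheme == "path":
                        coef = np.linalg.solve(C[np.ix_(pr, pr)], C[pr, j])
                    elif scheme == "factor":
                        coef = C[pr, j]
                    else:  # centroid
                        coef = np.sign(C[pr, j])
                    z = z + Y[:, pr] @ coef
                if su.size:
                    if scheme == "centroid":
                        z = z + Y[:, su] @ np.sign(C[su, j])
                    else:  # path & factor: successor correlations
                        z = z + Y[:, su] @ C[su, j]
                Z[:, j] = z
            delta = 0.0
            for j, b in enumerate(self.blocks):
                zj = Z[:, j]
                zsd = zj.std(ddof=1)
                if zsd <= 0:
                    raise ZeroDivisionError(
                        f"degenerate inner proxy for {self.constructs[j]!r}"
                    )
                w = X[:, b].T @ (zj / zsd) / (n - 1)  # Mode A: corr(x, proxy)
                sd = (X[:, b] @ w).std(ddof=1)
                if sd <= 0:
                    raise ZeroDivisionError(f"zero-variance score for {self.constructs[j]!r}")
                w = w / sd
                delta = max(delta, float(np.max(np.abs(w - W[j]))))
                W[j] = w
            _scores()
            if delta < tol:
                break
        else:
            raise PLSConvergenceError(
                f"outer weights did not converge in {max_iter} iterations "
                f"(last max change {delta:.3e})"
            )

        loadings = [X[:, b].T @ Y[:, j] / (n - 1) for j, b in enumerate(self.blocks)]
        # sign alignment: dominant |loading| of each block loads positively
        for j, lam in enumerate(loadings):
            if lam[np.argmax(np.abs(lam))] < 0:
                Y[:, j] *= -1
                W[j] = -W[j]
                loadings[j] = -lam
        C = (Y.T @ Y) / (n - 1)
        betas: dict[tuple[int, int], float] = {}
        r2: dict[int, float] = {}
        for j in range(k):
            pr = self.preds[j]
            if pr.size == 0:
                continue
            coef = np.linalg.solve(C[np.ix_(pr, pr)], C[pr, j])
            for p, b in zip(pr, coef):
                betas[(int(p), j)] = float(b)
            r2[j] = float(coef @ C[pr, j])
        return W, Y, loadings, betas, r2, n_iter


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ZeroDivisionError("zero-variance indicator")
    return (X - X.mean(axis=0)) / sd


# ---------------------------------------------------------------------------
# Indirect-effect enumeration
# ---------------------------------------------------------------------------


def enumerate_indirect(
    path_coefficients: dict[tuple[str, str], float],
    model: SemModel,
    source: str,
    target: str,
) -> list[tuple[tuple[str, ...], float]]:
    """All directed paths of length >= 2 from source to target with their
    products of path coefficients, in deterministic (lexicographic by
    construct order) order."""
    g = nx.DiGraph(list(path_coefficients))
    if source not in g or target not in g:
        return []
    order = {c: i for i, c in enumerate(model.constructs)}
    out = []
    for seq in nx.all_simple_paths(g, source, target):
        if len(seq) < 3:
            continue
        prod = 1.0
        for e in zip(seq[:-1], seq[1:]):
            prod *= path_coefficients[e]
        out.append((tuple(seq), prod))
    out.sort(key=lambda item: [order[c] for c in item[0]])
    return out


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------


@dataclass
class BootstrapInference:
    """Bootstrap SEs, t/p values and BCa intervals for paths and indirect
    effects.  CI bounds default to the 5% and 95% quantile levels (a 90%
    bias-corrected-and-accelerated interval)."""

    n_boot: int
    seed: int
    ci_levels: tuple[float, float]
    per_edge: dict[tuple[str, str], dict[str, float]]
    per_indirect: dict[str, dict[str, float]]
    loading_p: dict[str, float]
    n_redrawn: int = 0
    flags: list[str] = field(default_factory=list)

    def edge_frame(self) -> pd.DataFrame:
        rows = [{"path": f"{s} -> {t}", **st} for (s, t), st in self.per_edge.items()]
        return pd.DataFrame(rows)


@dataclass
class MediationResult:
    """Decomposition of a source->target effect into direct and indirect
    components with a mediation classification."""

    source: str
    target: str
    direct: float
    direct_significant: bool
    specific_indirect: list[tuple[tuple[str, ...], float, bool]]
    total_indirect: float
    total_indirect_significant: bool
    total_effect: float
    classification: str
    proportion_mediated: float


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class PLSPathModel:
    """PLS path model bound to a data table.

    Parameters
    ----------
    data
        Complete rectangular table containing every indicator column of
        ``model``.  Columns are standardized internally; any affine
        rescaling of a raw indicator leaves all results unchanged.
    model
        The :class:`SemModel` specification.
    scheme
        Inner weighting scheme: ``"path"`` (default), ``"factor"`` or
        ``"centroid"``.
    """

    def __init__(self, data: pd.DataFrame, model: SemModel, scheme: str = "path"):
        missing = [c for c in model.indicators if c not in data.columns]
        if missing:
            raise ValueError(f"indicator columns absent from data: {missing}")
        if data[model.indicators].isna().any().any():
            raise ValueError("data contain missing cells; impute before fitting")
        if scheme not in ("path", "factor", "centroid"):
            raise ValueError(f"unknown scheme {scheme!r}")
        self.data = data
        self.model = model
        self.scheme = scheme
        self._core = _Core(model)
        self._raw = data[model.indicators].to_numpy(dtype=float)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, model: SemModel, **kw) -> "PLSPathModel":
        return cls(data, model, **kw)

    def fit(self, tol: float = 1e-7, max_iter: int = 300) -> "PLSPathResults":
        X = _standardize(self._raw)
        W, Y, lam, betas, r2, n_iter = self._core.fit(
            X, scheme=self.scheme, tol=tol, max_iter=max_iter
        )
        return PLSPathResults(self, X, W, Y, lam, betas, r2, n_iter, tol, max_iter)


class PLSPathResults:
    """Fitted PLS path model: estimates, diagnostics and inference."""

    def __init__(self, model_obj, X, W, Y, lam, betas, r2, n_iter, tol, max_iter):
        self.model_obj = model_obj
        self.model: SemModel = model_obj.model
        core = model_obj._core
        self._core = core
        self._raw = model_obj._raw
        self._X = X
        self._W = W
        self._lam = lam
        self._tol = tol
        self._max_iter = max_iter
        self.n = X.shape[0]
        self.n_iter = n_iter
        self.converged = True
        self.scores = pd.DataFrame(Y, columns=core.constructs,
                                   index=model_obj.data.index)
        self.weights = pd.Series(
            {x: W[j][i] for j, b in enumerate(core.blocks)
             for i, x in enumerate(self.model.blocks[core.constructs[j]])},
            name="weight",
        )
        self.loadings = pd.Series(
            {x: lam[j][i] for j, _ in enumerate(core.blocks)
             for i, x in enumerate(self.model.blocks[core.constructs[j]])},
            name="loading",
        )
        self.path_coefficients = {
            (core.constructs[p], core.constructs[q]): b for (p, q), b in betas.items()
        }
        self.r2 = {core.constructs[j]: v for j, v in r2.items()}
        self.r2_adj = {
            c: 1.0 - (1.0 - v) * (self.n - 1) / (self.n - len(self.model.predecessors(c)) - 1)
            for c, v in self.r2.items()
        }

    # -- measurement (outer) diagnostics ----------------------------------

    def _indicator_corr(self) -> np.ndarray:
        n = self.n
        return (self._X.T @ self._X) / (n - 1)

    def outer_assessment(self) -> pd.DataFrame:
        """Per-construct AVE, Cronbach's alpha, rho_A and rho_C.

        Single-indicator constructs are reported as 1 and flagged as not
        assessable."""
        R = self._indicator_corr()
        rows = []
        for j, c in enumerate(self._core.constructs):
            b = self._core.blocks[j]
            lam = self._lam[j]
            single = len(b) == 1
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rows.append({
                    "construct": c,
                    "n_indicators": len(b),
                    "ave": 1.0 if single else rel.ave(lam),
                    "alpha": 1.0 if single else rel.cronbach_alpha(R[np.ix_(b, b)]),
                    "rho_a": 1.0 if single else rel.rho_a(self._W[j], R[np.ix_(b, b)]),
                    "rho_c": 1.0 if single else rel.rho_c(lam),
                    "assessable": not single,
                })
        return pd.DataFrame(rows).set_index("construct")

    def htmt_matrix(self) -> pd.DataFrame:
        """HTMT for every construct pair (single-indicator pairs fall back
        to the plain indicator correlation)."""
        R = self._indicator_corr()
        cs = self._core.constructs
        out = pd.DataFrame(np.eye(len(cs)), index=cs, columns=cs)
        for i, a in enumerate(cs):
            for j in range(i + 1, len(cs)):
                b = cs[j]
                v = rel.htmt(R, list(self._core.blocks[i]), list(self._core.blocks[j]))
                out.loc[a, b] = out.loc[b, a] = v
        return out

    # -- structural (inner) diagnostics -----------------------------------

    def f2(self) -> dict[tuple[str, str], float]:
        """Effect size f2 per structural edge (R2 change on dropping the
        predictor, relative to unexplained variance)."""
        C = self.scores.corr().to_numpy()
        idx = self._core.cindex
        out = {}
        for c in self.model.endogenous:
            preds = self.model.predecessors(c)
            pj = [idx[p] for p in preds]
            j = idx[c]
            r2_full = self.r2[c]
            for p in preds:
                rest = [idx[q] for q in preds if q != p]
                if rest:
                    coef = np.linalg.solve(C[np.ix_(rest, rest)], C[rest, j])
                    r2_red = float(coef @ C[rest, j])
                else:
                    r2_red = 0.0
                out[(p, c)] = rel.f_squared(r2_full, min(r2_red, r2_full))
        return out

    def vif(self, construct: str) -> dict[str, float]:
        """VIF of each predictor of ``construct`` from the score
        correlations (1.0 for a lone predictor)."""
        preds = self.model.predecessors(construct)
        if not preds:
            raise ValueError(f"{construct!r} has no predecessors")
        if len(preds) == 1:
            return {preds[0]: 1.0}
        C = self.scores[preds].corr().to_numpy()
        out = {}
        for i, p in enumerate(preds):
            rest = [j for j in range(len(preds)) if j != i]
            sub = C[np.ix_(rest, rest)]
            v = C[rest, i]
            try:
                r2 = float(v @ np.linalg.solve(sub, v))
            except np.linalg.LinAlgError:
                r2 = 1.0
            out[p] = rel.vif_from_r2(min(r2, 1.0))
        return out

    def implied_indicator_corr(self) -> pd.DataFrame:
        """Model-implied indicator correlations rebuilt from the fitted
        loadings and construct score correlations with the composite
        formula (within-block off-diagonals solved in least squares)."""
        C = self.scores.corr().to_numpy()
        core = self._core
        p = len(core.indicators)
        R = np.eye(p)
        for j, a in enumerate(core.constructs):
            lam_a = self._lam[j]
            ba = core.blocks[j]
            R[np.ix_(ba, ba)] = _within_lstsq(lam_a)
            for q in range(j + 1, len(core.constructs)):
                lam_b = self._lam[q]
                bb = core.blocks[q]
                blk = np.outer(lam_a, lam_b) * C[j, q]
                R[np.ix_(ba, bb)] = blk
                R[np.ix_(bb, ba)] = blk.T
        return pd.DataFrame(R, index=core.indicators, columns=core.indicators)

    def srmr(self) -> float:
        """SRMR between the empirical and model-implied indicator
        correlation matrices."""
        return rel.srmr(self._indicator_corr(), self.implied_indicator_corr().to_numpy())

    # -- effects ----------------------------------------------------------

    def indirect_effects(self, source: str, target: str):
        return enumerate_indirect(self.path_coefficients, self.model, source, target)

    def total_effect(self, source: str, target: str) -> float:
        direct = self.path_coefficients.get((source, target), 0.0)
        return direct + sum(v for _, v in self.indirect_effects(source, target))

    # -- refit machinery for resampling -----------------------------------

    def _fit_arrays(self, raw: np.ndarray):
        """Refit on a raw (unstandardized) row-resampled matrix, aligning
        construct-score signs to this solution's loading pattern."""
        X = _standardize(raw)
        W, Y, lam, betas, r2, _ = self._core.fit(
            X, scheme=self.model_obj.scheme, tol=self._tol, max_iter=self._max_iter
        )
        flips = np.ones(len(lam))
        for j, l in enumerate(lam):
            if float(l @ self._lam[j]) < 0:
                flips[j] = -1.0
                lam[j] = -l
        betas = {e: b * flips[e[0]] * flips[e[1]] for e, b in betas.items()}
        return lam, betas

    def bootstrap(
        self,
        n_boot: int = 10_000,
        seed: int = 0,
        ci_levels: tuple[float, float] = (0.05, 0.95),
        indirect_pairs: list[tuple[str, str]] | None = None,
        jackknife: bool = True,
    ) -> BootstrapInference:
        """Row-resampling bootstrap of the full estimator.

        Every resample refits the complete pipeline (standardization,
        weight iteration, structural OLS) and is sign-aligned to the
        original solution before aggregation.  Reported per edge and per
        enumerated indirect/total effect: bootstrap SE, t = estimate/SE,
        two-sided p from the t distribution with n-1 df, and
        bias-corrected-and-accelerated interval bounds at ``ci_levels``.
        Resamples in which an indicator has zero variance are redrawn
        (counted; capped at 10% of ``n_boot``).
        """
        if n_boot < 2:
            raise ValueError("n_boot must be at least 2")
        rng = np.random.default_rng(seed)
        core = self._core
        idx = core.cindex
        edges = list(self.model.paths)

        if indirect_pairs is None:
            g = self.model.graph()
            indirect_pairs = [
                (s, t)
                for s in self.model.constructs
                for t in self.model.constructs
                if s != t and any(
                    len(q) >= 3 for q in nx.all_simple_paths(g, s, t)
                )
            ]
        specific = {
            pair: [seq for seq, _ in self.indirect_effects(*pair)] for pair in indirect_pairs
        }

        def _collect(betas: dict[tuple[int, int], float]) -> np.ndarray:
            by_name = {
                (core.constructs[p], core.constructs[q]): b for (p, q), b in betas.items()
            }
            vals = [by_name.get(e, 0.0) for e in edges]
            for pair in indirect_pairs:
                tot_ind = 0.0
                for seq in specific[pair]:
                    prod = 1.0
                    for e in zip(seq[:-1], seq[1:]):
                        prod *= by_name.get(e, 0.0)
                    vals.append(prod)
                    tot_ind += prod
                direct = by_name.get(pair, 0.0)
                vals.append(tot_ind)
                vals.append(direct + tot_ind)
            return np.array(vals)

        labels: list[object] = list(edges)
        for pair in indirect_pairs:
            for seq in specific[pair]:
                labels.append(" -> ".join(seq))
            labels.append(f"total_indirect: {pair[0]} -> {pair[1]}")
            labels.append(f"total_effect: {pair[0]} -> {pair[1]}")

        point = _collect({(idx[s], idx[t]): b for (s, t), b in self.path_coefficients.items()})

        n = self.n
        stats_boot = np.empty((n_boot, len(labels)))
        load_boot = np.empty((n_boot, len(self.loadings)))
        redraws = 0
        max_redraws = max(1, n_boot // 10)
        b = 0
        while b < n_boot:
            rows = rng.integers(0, n, size=n)
            try:
                lam, betas = self._fit_arrays(self._raw[rows])
            except ZeroDivisionError:
                redraws += 1
                if redraws > max_redraws:
                    raise RuntimeError(
                        "bootstrap redraw rate exceeded 10%: too many degenerate resamples"
                    )
                continue
            stats_boot[b] = _collect(betas)
            load_boot[b] = np.concatenate(lam)
            b += 1

        # jackknife for the BCa acceleration constant (bias-corrected
        # percentile only, i.e. acceleration 0, when disabled)
        accel = np.zeros(len(labels))
        if jackknife:
            jack = np.empty((n, len(labels)))
            mask = np.ones(n, dtype=bool)
            for i in range(n):
                mask[i] = False
                try:
                    _, betas = self._fit_arrays(self._raw[mask])
                    jack[i] = _collect(betas)
                except ZeroDivisionError:
                    jack[i] = point
                mask[i] = True
            jm = jack.mean(axis=0)
            d = jm - jack
            denom = np.sum(d**2, axis=0) ** 1.5
            accel = np.where(
                denom > 0, np.sum(d**3, axis=0) / (6.0 * np.maximum(denom, 1e-300)), 0.0
            )

        flags: list[str] = []
        per: dict[object, dict[str, float]] = {}
        for j, label in enumerate(labels):
            theta = float(point[j])
            bs = stats_boot[:, j]
            se = float(bs.std(ddof=1))
            if se < 1e-12:
                per[label] = {"estimate": theta, "se": se, "t": float("inf") if theta else 0.0,
                              "p": 0.0 if theta else 1.0, "ci_low": theta, "ci_high": theta}
                continue
            t = theta / se
            p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
            lo, hi = _bca_interval(bs, theta, float(accel[j]), ci_levels)
            if not (lo <= theta <= hi):
                flags.append(f"BCa interval excludes the point estimate for {label}")
            per[label] = {"estimate": theta, "se": se, "t": t, "p": p,
                          "ci_low": lo, "ci_high": hi}

        load_se = load_boot.std(axis=0, ddof=1)
        lam0 = np.concatenate(self._lam)
        loading_p = {}
        for name, l0, se in zip(self.loadings.index, lam0, load_se):
            if se < 1e-12:
                loading_p[name] = 0.0 if abs(l0) > 0 else 1.0
            else:
                loading_p[name] = float(2.0 * stats.t.sf(abs(l0 / se), df=n - 1))

        return BootstrapInference(
            n_boot=n_boot,
            seed=seed,
            ci_levels=ci_levels,
            per_edge={e: per[e] for e in edges},
            per_indirect={lab: per[lab] for lab in labels if not isinstance(lab, tuple)},
            loading_p=loading_p,
            n_redrawn=redraws,
            flags=flags,
        )

    # -- mediation ---------------------------------------------------------

    def mediation(
        self,
        source: str,
        target: str,
        inference: BootstrapInference | None = None,
        n_boot: int = 5000,
        seed: int = 0,
        alpha: float = 0.05,
    ) -> MediationResult:
        """Mediation decomposition of the source->target effect.

        Classification: direct and total-indirect both significant with
        the same sign -> complementary (partial mediation); opposite signs
        -> competitive; only the indirect significant -> indirect-only
        (full mediation); only the direct -> direct-only; neither ->
        no-effect.  ``proportion_mediated`` is |indirect| /
        (|direct| + |indirect|).
        """
        if inference is None:
            inference = self.bootstrap(n_boot=n_boot, seed=seed,
                                       indirect_pairs=[(source, target)])
        direct = self.path_coefficients.get((source, target), 0.0)
        has_edge = (source, target) in self.path_coefficients
        paths = self.indirect_effects(source, target)
        total_ind = sum(v for _, v in paths)

        def _sig(label) -> bool:
            entry = inference.per_indirect.get(label) if not isinstance(label, tuple) \
                else inference.per_edge.get(label)
            return bool(entry is not None and entry["p"] < alpha)

        direct_sig = has_edge and _sig((source, target))
        ti_label = f"total_indirect: {source} -> {target}"
        indirect_sig = bool(paths) and _sig(ti_label)
        specific = [
            (seq, val, _sig(" -> ".join(seq))) for seq, val in paths
        ]
        if direct_sig and indirect_sig:
            cls = "complementary" if direct * total_ind >= 0 else "competitive"
        elif indirect_sig:
            cls = "indirect-only"
        elif direct_sig:
            cls = "direct-only"
        else:
            cls = "no-effect"
        denom = abs(direct) + abs(total_ind)
        return MediationResult(
            source=source,
            target=target,
            direct=direct,
            direct_significant=direct_sig,
            specific_indirect=specific,
            total_indirect=total_ind,
            total_indirect_significant=indirect_sig,
            total_effect=direct + total_ind,
            classification=cls,
            proportion_mediated=abs(total_ind) / denom if denom > 0 else 0.0,
        )

    # -- reporting ---------------------------------------------------------

    def path_frame(self) -> pd.DataFrame:
        rows = [
            {"path": f"{s} -> {t}", "beta": b} for (s, t), b in self.path_coefficients.items()
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "PLS path model (Mode A, %s weighting scheme)" % self.model_obj.scheme,
            f"n = {self.n}, constructs = {len(self.model.constructs)}, "
            f"indicators = {len(self.model.indicators)}",
            f"converged in {self.n_iter} iterations; SRMR = {self.srmr():.4f}",
            "",
            "Structural paths:",
        ]
        f2 = self.f2()
        for (s, t), b in self.path_coefficients.items():
            lines.append(f"  {s} -> {t}: beta = {b:+.3f}  f2 = {f2[(s, t)]:.3f} "
                         f"({rel.classify_f2(f2[(s, t)])})")
        lines.append("")
        lines.append("R2 (adjusted):")
        for c, v in self.r2.items():
            lines.append(f"  {c}: {v:.3f} ({self.r2_adj[c]:.3f})")
        return "\n".join(lines)


def _within_lstsq(lam: np.ndarray) -> np.ndarray:
    """Within-block implied correlations: least-squares solution of the
    composite-consistency condition S_b lam = (lam'lam) lam (exact when
    loadings are equal; min-norm compromise otherwise)."""
    k = len(lam)
    if k == 1:
        return np.ones((1, 1))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    A = np.zeros((k, len(pairs)))
    for col, (i, j) in enumerate(pairs):
        A[i, col] = lam[j]
        A[j, col] = lam[i]
    b = (float(lam @ lam) - 1.0) * lam
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    S = np.eye(k)
    for col, (i, j) in enumerate(pairs):
        S[i, j] = S[j, i] = float(np.clip(sol[col], -1.0, 1.0))
    return S


def _bca_interval(boot: np.ndarray, theta: float, accel: float,
                  levels: tuple[float, float]) -> tuple[float, float]:
    """Bias-corrected-and-accelerated quantile bounds."""
    B = boot.size
    prop = (np.sum(boot < theta) + 0.5 * np.sum(boot == theta)) / B
    prop = min(max(prop, 0.5 / B), 1 - 0.5 / B)
    z0 = stats.norm.ppf(prop)
    out = []
    for a in levels:
        za = stats.norm.ppf(a)
        adj = stats.norm.cdf(z0 + (z0 + za) / (1.0 - accel * (z0 + za)))
        out.append(float(np.quantile(boot, adj)))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Indicator pruning
# ---------------------------------------------------------------------------


def prune_indicators(
    data: pd.DataFrame,
    model: SemModel,
    loading_cutoff: float = 0.5,
    p_cutoff: float = 0.05,
    n_boot: int = 500,
    seed: int = 0,
) -> SemModel:
    """Iteratively remove weak indicators from the measurement model.

    At each step the model is refitted and the indicator with the lowest
    |loading| among the offenders (|loading| < ``loading_cutoff`` or
    bootstrap loading p > ``p_cutoff``; the p criterion is skipped when
    ``n_boot`` is 0) is removed; ties break by block order then indicator
    order.  A block is never emptied: its last indicator is retained with
    a warning.
    """
    current = model
    while True:
        res = PLSPathModel(data, current).fit()
        loading_p = {}
        if n_boot:
            loading_p = res.bootstrap(n_boot=n_boot, seed=seed, indirect_pairs=[],
                                      jackknife=False).loading_p
        offenders = []
        order = {x: i for i, x in enumerate(current.indicators)}
        for x in current.indicators:
            lam = abs(float(res.loadings[x]))
            bad = lam < loading_cutoff or loading_p.get(x, 0.0) > p_cutoff
            if bad:
                if len(current.blocks[current.block_of(x)]) == 1:
                    warnings.warn(
                        f"indicator {x!r} is weak but is the last of its block; retained"
                    )
                else:
                    offenders.append((lam, order[x], x))
        if not offenders:
            return current
        offenders.sort()
        current = current.drop_indicator(offenders[0][2])
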