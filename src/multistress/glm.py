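"""GLM screening of stressor effects with RESI effect sizes.

Each biological response is regressed on the experimental stressors with a
normal-error GLM (identity or log link).  Coefficients are tested with
Wald chi-square statistics; non-significant two-way interactions are
pruned in a single pass.  Effect sizes use the robust effect size index

    S = sqrt(max(0, (T2 - m) / n))

for a Wald chi-square T2 on m degrees of freedom, with the standard
conversions f2 = S**2 and Cohen's d = 2 S.  A noncentral-F power routine
returns the minimum sample size for a single regression coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GLMSpec",
    "GLMResult",
    "ResiEstimate",
    "fit_glm",
    "prune_interactions",
    "resi_s",
    "resi_from_wald",
    "classify_s",
    "required_sample_size",
    "run_glm_battery",
    "DEFAULT_BATTERY",
]


@dataclass(frozen=True)
class GLMSpec:
    """Specification of one normal-error GLM.

    ``categorical`` maps predictor name -> reference level (treatment
    coding); other predictors are continuous.  ``interactions`` lists
    candidate two-way interactions by predictor name.
    """

    response: str
    predictors: tuple[str, ...]
    link: str = "identity"
    categorical: dict[str, object] = field(default_factory=dict)
    interactions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.link not in ("identity", "log"):
            raise ValueError(f"link must be 'identity' or 'log', got {self.link!r}")
        if not self.predictors:
            raise ValueError("at least one predictor is required")
        object.__setattr__(self, "predictors", tuple(self.predictors))
        object.__setattr__(self, "interactions", tuple(tuple(p) for p in self.interactions))


@dataclass
class GLMResult:
    """Estimates, Wald inference and goodness-of-fit for one GLM."""

    spec: GLMSpec
    terms: list[str]
    params: pd.Series
    cov: pd.DataFrame
    estimates: dict[str, tuple[float, float, float, float]]  # coef, se, wald, p
    deviance: float
    pearson_chi2: float
    df_resid: int
    nobs: int
    converged: bool
    term_groups: dict[str, list[str]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            {"term": t, "estimate": c, "se": s, "wald": w, "p": p}
            for t, (c, s, w, p) in self.estimates.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ResiEstimate:
    """Robust effect size index with standard conversions."""

    s_beta: float
    f_squared: float
    cohens_d: float
    category: str


def _design_matrix(table: pd.DataFrame, spec: GLMSpec) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Treatment-coded design matrix with intercept.

    Returns the matrix and a map predictor -> its column names (a
    categorical predictor with L levels spans L-1 columns).
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(table))}
    groups: dict[str, list[str]] = {}
    coded: dict[str, list[str]] = {}
    for name in spec.predictors:
        if name not in table.columns:
            raise ValueError(f"predictor {name!r} not in table")
        if name in spec.categorical:
            ref = spec.categorical[name]
            levels = sorted(table[name].astype(str).unique())
            if str(ref) not in levels:
                raise ValueError(f"reference level {ref!r} absent from {name!r}")
            members = []
            for lev in levels:
                if lev == str(ref):
                    continue
                label = f"{name}({lev})"
                cols[label] = (table[name].astype(str) == lev).astype(float).to_numpy()
                members.append(label)
        else:
            label = name
            cols[label] = table[name].astype(float).to_numpy()
            members = [label]
        groups[name] = members
        coded[name] = members
    for a, b in spec.interactions:
        members = []
        for ca in coded[a]:
            for cb in coded[b]:
                label = f"{ca}:{cb}"
                cols[label] = cols[ca] * cols[cb]
                members.append(label)
        groups[f"{a}:{b}"] = members
    X = pd.DataFrame(cols, index=table.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design ({rank} < {X.shape[1]}); aliased terms present")
    return X, groups


def fit_glm(table: pd.DataFrame, spec: GLMSpec) -> GLMResult:
    """Fit a normal-error GLM by IRLS and return Wald inference.

    Wald statistics are ``(coef/se)**2`` referred to a chi-square with one
    degree of freedom; deviance and the Pearson chi-square are returned as
    goodness-of-fit summaries.
    """
    if table[spec.response].isna().any() or table[list(spec.predictors)].isna().any().any():
        raise ValueError("fit_glm requires a complete table; impute first")
    X, groups = _design_matrix(table, spec)
    y = table[spec.response].astype(float).to_numpy()
    link = sm.families.links.Log() if spec.link == "log" else sm.families.links.Identity()
    model = sm.GLM(y, X.to_numpy(), family=sm.families.Gaussian(link=link))
    res = model.fit(maxiter=200, tol=1e-10)
    if not res.converged:
        raise RuntimeError(
            f"GLM for {spec.response!r} did not converge "
            f"(deviance trace: {getattr(res, 'fit_history', {}).get('deviance', 'n/a')})"
        )
    params = pd.Series(res.params, index=X.columns)
    cov = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    se = pd.Series(np.sqrt(np.diag(cov)), index=X.columns)
    wald = (params / se) ** 2
    pvals = stats.chi2.sf(wald, df=1)
    estimates = {
        t: (float(params[t]), float(se[t]), float(wald[t]), float(p))
        for t, p in zip(X.columns, pvals)
    }
    return GLMResult(
        spec=spec,
        terms=list(X.columns),
        params=params,
        cov=cov,
        estimates=estimates,
        deviance=float(res.deviance),
        pearson_chi2=float(res.pearson_chi2),
        df_resid=int(res.df_resid),
        nobs=int(res.nobs),
        converged=bool(res.converged),
        term_groups=groups,
    )


def _group_wald(result: GLMResult, group: str) -> tuple[float, int]:
    """Wald chi-square for all columns of one predictor/interaction group."""
    members = result.term_groups[group]
    b = result.params[members].to_numpy()
    C = result.cov.loc[members, members].to_numpy()
    t2 = float(b @ np.linalg.solve(C, b))
    return t2, len(members)


def prune_interactions(table: pd.DataFrame, spec: GLMSpec, alpha: float = 0.05) -> GLMSpec:
    """Drop all non-significant two-way interactions in one pass.

    The full model (all candidate interactions) is fitted once; every
    interaction whose group Wald p-value is >= ``alpha`` is removed
    simultaneously.
    """
    if not spec.interactions:
        return spec
    full = fit_glm(table, spec)
    keep = []
    for a, b in spec.interactions:
        t2, m = _group_wald(full, f"{a}:{b}")
        p = float(stats.chi2.sf(t2, df=m))
        if p < alpha:
            keep.append((a, b))
    return replace(spec, interactions=tuple(keep))


def resi_from_wald(t2: float, m: int, n: int) -> ResiEstimate:
    """RESI point estimate from a Wald chi-square ``t2`` on ``m`` df."""
    if m < 1 or n <= 0:
        raise ValueError("m >= 1 and n > 0 required")
    s = float(np.sqrt(max(0.0, (t2 - m) / n)))
    return ResiEstimate(s_beta=s, f_squared=s * s, cohens_d=2 * s, category=classify_s(s))


def resi_s(full: GLMResult, reduced: GLMResult, n: int | None = None) -> ResiEstimate:
    """RESI for the term(s) present in ``full`` but not in ``reduced``.

    The reduced model must be nested in the full model; the Wald
    chi-square for the dropped coefficients is taken from the full model's
    estimated covariance.
    """
    dropped = [t for t in full.terms if t not in reduced.terms]
    if not dropped or any(t not in full.terms for t in reduced.terms):
        raise ValueError("reduced model is not nested in the full model")
    n = int(n if n is not None else full.nobs)
    if n <= len(full.terms):
        raise ValueError("n must exceed the number of parameters in the full model")
    b = full.params[dropped].to_numpy()
    C = full.cov.loc[dropped, dropped].to_numpy()
    t2 = float(b @ np.linalg.solve(C, b))
    return resi_from_wald(t2, m=len(dropped), n=n)


#: Half-open RESI magnitude bands.
_S_BANDS = ((0.1, "small"), (0.25, "medium"), (0.4, "large"))


def classify_s(s_beta: float) -> str:
    """Classify an RESI value: [0, 0.1) small, [0.1, 0.25) medium,
    [0.25, 0.4) large, >= 0.4 very large."""
    if s_beta < 0:
        raise ValueError(f"s_beta must be non-negative, got {s_beta}")
    for upper, label in _S_BANDS:
        if s_beta < upper:
            return label
    return "very large"


def required_sample_size(
    f_squared: float,
    alpha: float = 0.05,
    power: float = 0.80,
    n_predictors: int = 1,
    n_max: int = 10**6,
) -> int:
    """Minimum n for the noncentral-F test of one regression coefficient.

    The test has numerator df 1, denominator df ``n - n_predictors - 1``
    and noncentrality ``f_squared * n``; the smallest integer n attaining
    the requested power at level ``alpha`` is returned.
    """
    if f_squared <= 0:
        raise ValueError("f_squared must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")

    def attained(n: int) -> float:
        df2 = n - n_predictors - 1
        if df2 < 1:
            return 0.0
        crit = stats.f.isf(alpha, 1, df2)
        return float(stats.ncf.sf(crit, 1, df2, f_squared * n))

    lo = n_predictors + 2
    hi = lo
    while attained(hi) < power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"requested power unreachable for any n <= {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if attained(mid) >= power:
            hi = mid
        else:
            lo = mid + 1
    return int(lo)


# ---------------------------------------------------------------------------
# Battery runner
# ---------------------------------------------------------------------------

#: response -> (link, box-cox transform before fitting) for the study's
#: ten biological responses.
DEFAULT_BATTERY: dict[str, tuple[str, bool]] = {
    "chl_a_c": ("log", True),
    "carotenoids": ("log", True),
    "fv_fm": ("log", False),
    "y_ii": ("identity", True),
    "npq": ("identity", False),
    "orac": ("log", True),
    "pct_c": ("identity", False),
    "pct_h": ("identity", False),
    "pct_n": ("identity", False),
    "cn_ratio": ("identity", False),
}

_STRESSORS = ("pah_activity", "turbulence", "turbidity", "mp")
_CATEGORICAL = {"turbulence": "0", "mp": "0"}
_CANDIDATE_INTERACTIONS = (("mp", "pah_activity"), ("mp", "turbidity"),
                           ("pah_activity", "turbidity"))


def run_glm_battery(
    table: pd.DataFrame,
    battery: dict[str, tuple[str, bool]] | None = None,
    alpha: float = 0.05,
    prune: bool = True,
) -> pd.DataFrame:
    """Fit the stressor GLM for every response and report a tidy table.

    For each response the candidate two-way interactions are pruned, the
    final model is fitted, and RESI is attached to significant predictors
    (full-vs-reduced comparison dropping that predictor).  Output columns:
    response, predictor, link, estimate, se, wald, p, s_beta.
    """
    from .preprocess import boxcox_mle, boxcox_transform

    battery = battery or {
        r: cfg for r, cfg in DEFAULT_BATTERY.items() if r in table.columns
    }
    rows = []
    for response, (link, use_boxcox) in battery.items():
        work = table.copy()
        if use_boxcox:
            fit = boxcox_mle(work[response].to_numpy(), column=response)
            work[response] = boxcox_transform(work[response].to_numpy(), fit.lam)
        spec = GLMSpec(
            response=response,
            predictors=tuple(s for s in _STRESSORS if s in work.columns),
            link=link,
            categorical={k: v for k, v in _CATEGORICAL.items() if k in work.columns},
            interactions=_CANDIDATE_INTERACTIONS if prune else (),
        )
        if prune:
            spec = prune_interactions(work, spec, alpha=alpha)
        final = fit_glm(work, spec)
        for group, members in final.term_groups.items():
            t2, m = _group_wald(final, group)
            p = float(stats.chi2.sf(t2, df=m))
            coef, se, wald, p1 = final.estimates[members[0]] if len(members) == 1 else (
                np.nan, np.nan, t2, p)
            s_beta = np.nan
            if p < alpha:
                s_beta = resi_from_wald(t2, m, final.nobs).s_beta
            rows.append({
                "response": response,
                "predictor": members[0] if len(members) == 1 else group,
                "link": link,
                "estimate": coef,
                "se": se,
                "wald": wald if len(members) == 1 else t2,
                "p": p1 if len(members) == 1 else p,
                "s_beta": s_beta,
            })
    return pd.DataFrame(rows)
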