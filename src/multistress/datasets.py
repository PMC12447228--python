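"""Synthetic data generation for the multi-stressor algal study system.

Two generation modes are provided:

* **population mode** — draws from a multivariate normal whose correlation
  matrix is implied by a recursive standardized structural system together
  with a composite-consistent measurement model.  Construct scores in the
  generated data are *exact* loading-weighted composites of their
  indicators, the regime under which a PLS path estimator is consistent,
  so generating path coefficients are recoverable at large n.
* **experiment mode** — emulates the 2x2x2 factorial exposure design
  (PAH chemical activity 0 vs 0.14, microplastics absent/present,
  turbulence low/high, 3 replicates, n = 24) with turbidity measured in
  NTU, realistic response scales and a handful of missing photometry
  cells.

The default parameter values describe the eight-construct stressor ->
response system of the study: polycyclic aromatic hydrocarbons (PAHs),
microplastics (MPs) and turbulence acting on a filamentous macroalga
through sediment resuspension, pigment content, photosystem II (PSII)
performance, antioxidant capacity and elemental stoichiometry.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model_spec import ModelSpecError, SemModel

__all__ = [
    "InvalidParametersError",
    "ExperimentDesign",
    "PopulationModel",
    "implied_construct_correlations",
    "implied_indicator_correlations",
    "sample_population",
    "sample_experiment",
    "study_model",
    "study_population",
    "STUDY_PATH_VALUES",
    "PHOTOMETRY_COLUMNS",
    "write_sample_table",
    "read_sample_table",
]


class InvalidParametersError(ValueError):
    """Population parameters do not yield a valid correlation structure."""


# ---------------------------------------------------------------------------
# Study system defaults
# ---------------------------------------------------------------------------

#: Standardized generating path coefficients of the full structural model:
#: stressors (PAH chemical activity, microplastics, turbulence) acting on
#: algal physiology directly and through sediment resuspension and pigments.
STUDY_PATH_VALUES: dict[tuple[str, str], float] = {
    ("turbulence", "sediment_resuspension"): 0.564,
    ("microplastics", "sediment_resuspension"): 0.382,
    ("sediment_resuspension", "pahs"): 0.099,
    ("pahs", "pigments"): -0.265,
    ("turbulence", "pigments"): -0.442,
    ("pahs", "antioxidant_capacity"): -0.004,
    ("sediment_resuspension", "antioxidant_capacity"): 0.568,
    ("pahs", "psii_performance"): -0.766,
    ("pigments", "psii_performance"): 0.200,
    ("antioxidant_capacity", "psii_performance"): -0.028,
    ("psii_performance", "elemental_ratios"): 0.494,
    ("sediment_resuspension", "elemental_ratios"): -0.684,
}

_FULL_BLOCKS = {
    "turbulence": ["turbulence"],
    "microplastics": ["mp"],
    "sediment_resuspension": ["turbidity"],
    "pahs": ["pah_activity"],
    "pigments": ["chl_a_c", "carotenoids"],
    "antioxidant_capacity": ["orac"],
    "psii_performance": ["fv_fm", "y_ii", "npq"],
    "elemental_ratios": ["pct_c", "pct_h", "pct_n", "cn_ratio"],
}

_PRUNED_BLOCKS = {
    **_FULL_BLOCKS,
    "psii_performance": ["fv_fm", "y_ii"],
    "elemental_ratios": ["pct_h", "cn_ratio"],
}

#: Photometry responses that may carry missing cells in experiment mode.
PHOTOMETRY_COLUMNS = ("fv_fm", "y_ii", "npq")

#: Location/scale used to put standardized response indicators on plausible
#: measurement scales (units: pigments mg g-1 dw, Fv/Fm and Y(II) unitless
#: quantum yields, ORAC umol TE g-1, elemental content %, C/N molar ratio).
RESPONSE_SCALES: dict[str, tuple[float, float]] = {
    "chl_a_c": (6.0, 1.0),
    "carotenoids": (3.0, 0.5),
    "fv_fm": (0.65, 0.06),
    "y_ii": (0.55, 0.05),
    "npq": (0.80, 0.20),
    "orac": (40.0, 8.0),
    "pct_c": (30.0, 2.0),
    "pct_h": (5.0, 0.4),
    "pct_n": (3.0, 0.3),
    "cn_ratio": (10.0, 1.0),
}

#: Population loadings used by the experiment-mode generator for the weak
#: indicators that a 0.5-loading screen should flag and remove.
WEAK_INDICATOR_LOADING = 0.3
_WEAK_INDICATORS = ("npq", "pct_c", "pct_n")


def study_model(pruned: bool = True) -> SemModel:
    """Default structural/measurement model of the study system.

    With ``pruned=True`` (default) the measurement model keeps only the
    indicators that survive the loading screen (NPQ, %C and %N dropped);
    ``pruned=False`` returns the full pre-screen indicator map.
    """
    blocks = _PRUNED_BLOCKS if pruned else _FULL_BLOCKS
    return SemModel(blocks={c: list(v) for c, v in blocks.items()},
                    paths=tuple(STUDY_PATH_VALUES))


def _default_loadings(model: SemModel, multi: float = 0.9) -> dict[str, float]:
    out: dict[str, float] = {}
    for construct, inds in model.blocks.items():
        for ind in inds:
            out[ind] = 1.0 if len(inds) == 1 else multi
    return out


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """A :class:`SemModel` plus generating values for data synthesis.

    ``path_values`` maps every structural edge to its standardized
    coefficient; ``loading_values`` maps every indicator to a loading in
    (0, 1] (single-indicator constructs must have loading 1).
    ``exo_correlations`` is the correlation matrix over exogenous
    constructs, identity by default (orthogonal by factorial design).
    """

    model: SemModel
    path_values: dict[tuple[str, str], float]
    loading_values: dict[str, float] = field(default_factory=dict)
    exo_correlations: np.ndarray | None = None
    n: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.model.paths) - {tuple(k) for k in self.path_values}
        if missing:
            raise InvalidParametersError(f"edges without a path value: {sorted(missing)}")
        object.__setattr__(
            self,
            "path_values",
            {tuple(k): float(v) for k, v in self.path_values.items() if tuple(k) in set(self.model.paths)},
        )
        for edge, beta in self.path_values.items():
            if abs(beta) > 1:
                raise InvalidParametersError(f"|beta| > 1 on edge {edge}: {beta}")
        loadings = dict(self.loading_values) if self.loading_values else _default_loadings(self.model)
        for construct, inds in self.model.blocks.items():
            for ind in inds:
                lam = float(loadings.get(ind, 1.0 if len(inds) == 1 else 0.9))
                if not 0.0 < lam <= 1.0:
                    raise InvalidParametersError(f"loading for {ind!r} outside (0, 1]: {lam}")
                if len(inds) == 1 and lam != 1.0:
                    raise InvalidParametersError(
                        f"single-indicator construct {construct!r} must have loading 1"
                    )
                loadings[ind] = lam
        object.__setattr__(self, "loading_values", loadings)

    def with_seed(self, seed: int) -> "PopulationModel":
        return replace(self, seed=int(seed))

    def loadings_of(self, construct: str) -> np.ndarray:
        return np.array([self.loading_values[i] for i in self.model.blocks[construct]])


def study_population(pruned: bool = True, n: int = 5000, seed: int = 0) -> PopulationModel:
    """Default population: study topology, default paths and loadings."""
    model = study_model(pruned=pruned)
    loadings = _default_loadings(model)
    if not pruned:
        for ind in _WEAK_INDICATORS:
            loadings[ind] = WEAK_INDICATOR_LOADING
    return PopulationModel(model=model, path_values=dict(STUDY_PATH_VALUES),
                           loading_values=loadings, n=n, seed=seed)


@dataclass(frozen=True)
class ExperimentDesign:
    """The 2x2x2 factorial exposure design with replication.

    Defaults reproduce the study layout: PAH chemical activity 0 vs 0.14,
    microplastics absent/present, turbulence low/high, 3 replicates
    (24 rows), turbidity within 0.8-3.9 NTU and 4 missing photometry
    cells (Fv/Fm, Y(II) or NPQ).
    """

    pah_levels: tuple[float, ...] = (0.0, 0.14)
    mp_levels: tuple[int, ...] = (0, 1)
    turbulence_levels: tuple[str, ...] = ("low", "high")
    replicates: int = 3
    turbidity_range: tuple[float, float] = (0.8, 3.9)
    n_missing: int = 4
    seed: int = 0

    @property
    def n_rows(self) -> int:
        return (len(self.pah_levels) * len(self.mp_levels)
                * len(self.turbulence_levels) * self.replicates)


# ---------------------------------------------------------------------------
# Implied correlation structure
# ---------------------------------------------------------------------------


def _construct_system(
    path_values: dict[tuple[str, str], float],
    model: SemModel,
    exo_correlations: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Construct correlation matrix and residual variances of the recursive
    standardized linear system (computed construct-by-construct in
    topological order)."""
    order = model.topological_order()
    idx = {c: i for i, c in enumerate(order)}
    k = len(order)
    exo = model.exogenous
    if exo_correlations is None:
        phi = np.eye(len(exo))
    else:
        phi = np.asarray(exo_correlations, dtype=float)
    if phi.shape != (len(exo), len(exo)):
        raise InvalidParametersError(
            f"exo_correlations must be {len(exo)}x{len(exo)} over {exo}"
        )
    if not np.allclose(phi, phi.T, atol=1e-10) or not np.allclose(np.diag(phi), 1.0, atol=1e-10):
        raise InvalidParametersError("exo_correlations must be symmetric with unit diagonal")
    if np.linalg.eigvalsh(phi).min() < -1e-10:
        raise InvalidParametersError("exo_correlations is not positive semi-definite")

    S = np.zeros((k, k))
    exo_idx = {c: j for j, c in enumerate(exo)}
    for a in exo:
        for b in exo:
            S[idx[a], idx[b]] = phi[exo_idx[a], exo_idx[b]]
    residual: dict[str, float] = {c: 1.0 for c in exo}

    for c in order:
        preds = model.predecessors(c)
        if not preds:
            continue
        i = idx[c]
        betas = np.array([path_values[(p, c)] for p in preds])
        pidx = [idx[p] for p in preds]
        # covariance with everything already placed
        for other in order:
            j = idx[other]
            if other == c:
                continue
            S[i, j] = S[j, i] = float(betas @ S[pidx, j])
        explained = float(betas @ S[np.ix_(pidx, pidx)] @ betas)
        if explained > 1.0 + 1e-10:
            raise InvalidParametersError(
                f"implied variance of {c!r} exceeds 1 (explained={explained:.4f}); "
                "residual variance would be negative"
            )
        residual[c] = max(0.0, 1.0 - explained)
        S[i, i] = 1.0

    out = pd.DataFrame(S, index=order, columns=order)
    cols = model.constructs
    return out.loc[cols, cols], residual


def implied_construct_correlations(
    path_values: dict[tuple[str, str], float],
    exo_correlations: np.ndarray | None = None,
    model: SemModel | None = None,
) -> pd.DataFrame:
    """Correlation matrix over constructs implied by the recursive
    standardized structural system.

    Exogenous constructs carry ``exo_correlations`` (identity when omitted);
    each endogenous construct is a linear combination of its predecessors
    plus an independent residual sized to give unit variance.
    """
    if model is None:
        blocks = {c: [c] for e in path_values for c in e}
        model = SemModel(blocks=blocks, paths=tuple(path_values))
    S, _ = _construct_system(path_values, model, exo_correlations)
    return S


def _within_block_correlations(lam: np.ndarray, construct: str) -> np.ndarray:
    """Unit-diagonal block matrix S_b with S_b @ lam = (lam'lam) lam, the
    condition under which the loading-weighted composite has unit variance
    and correlates lam_i with each indicator."""
    k = len(lam)
    if k == 1:
        return np.ones((1, 1))
    ss = float(lam @ lam)
    if np.allclose(lam, lam[0]):
        r = (k * lam[0] ** 2 - 1.0) / (k - 1.0)
        S = np.full((k, k), r)
        np.fill_diagonal(S, 1.0)
    else:
        # solve the linear system in the off-diagonal unknowns (min-norm)
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
        A = np.zeros((k, len(pairs)))
        for col, (i, j) in enumerate(pairs):
            A[i, col] = lam[j]
            A[j, col] = lam[i]
        b = (ss - 1.0) * lam
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ sol - b)) > 1e-8:
            raise InvalidParametersError(
                f"no unit-diagonal correlation matrix is composite-consistent "
                f"with the loadings of block {construct!r}: {lam.tolist()}"
            )
        S = np.eye(k)
        for col, (i, j) in enumerate(pairs):
            S[i, j] = S[j, i] = sol[col]
    if np.linalg.eigvalsh(S).min() < -1e-8 or np.max(np.abs(S)) > 1.0 + 1e-8:
        raise InvalidParametersError(
            f"composite-consistent within-block matrix of {construct!r} "
            "is not a valid correlation matrix"
        )
    return S


def implied_indicator_correlations(population: PopulationModel) -> pd.DataFrame:
    """Model-implied indicator correlation matrix (composite-consistent).

    Within a block the correlations satisfy the unit-composite-variance
    condition; across blocks ``corr(x_i in A, x_j in B) =
    lam_i * corr(A, B) * lam_j``.
    """
    model = population.model
    construct_corr, _ = _construct_system(
        population.path_values, model, population.exo_correlations
    )
    inds = model.indicators
    p = len(inds)
    R = np.zeros((p, p))
    offsets: dict[str, slice] = {}
    pos = 0
    for construct, block in model.blocks.items():
        offsets[construct] = slice(pos, pos + len(block))
        pos += len(block)
    for a, block_a in model.blocks.items():
        lam_a = population.loadings_of(a)
        R[offsets[a], offsets[a]] = _within_block_correlations(lam_a, a)
        for b, block_b in model.blocks.items():
            if a == b:
                continue
            lam_b = population.loadings_of(b)
            R[offsets[a], offsets[b]] = (
                np.outer(lam_a, lam_b) * construct_corr.loc[a, b]
            )
    if np.linalg.eigvalsh(R).min() < -1e-8:
        raise InvalidParametersError(
            "implied indicator correlation matrix is not positive semi-definite"
        )
    return pd.DataFrame(R, index=inds, columns=inds)


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _psd_factor(R: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(R)
    return V * np.sqrt(np.clip(w, 0.0, None))


def sample_population(population: PopulationModel) -> pd.DataFrame:
    """Draw ``population.n`` multivariate-normal rows with the implied
    indicator correlation matrix (zero mean, unit variance)."""
    R = implied_indicator_correlations(population)
    p = R.shape[0]
    if population.n < p + 2:
        raise InvalidParametersError(f"n must be at least {p + 2} for {p} indicators")
    rng = np.random.default_rng(population.seed)
    Z = rng.standard_normal((population.n, p))
    X = Z @ _psd_factor(R.to_numpy()).T
    return pd.DataFrame(X, columns=list(R.columns))


def sample_experiment(
    design: ExperimentDesign,
    population: PopulationModel | None = None,
    noise_scale: float = 1.0,
) -> pd.DataFrame:
    """Generate a factorial experiment table from the latent model.

    The design-controlled constructs (PAHs, microplastics, turbulence) are
    pinned to the standardized design columns; sediment resuspension is the
    standardized turbidity, itself generated as an increasing function of
    turbulence and MP presence plus noise, clipped to the design's NTU
    range.  Remaining endogenous constructs follow the structural recursion
    with Gaussian residuals; response indicators are loading-weighted
    construct scores plus unique noise, placed on plausible measurement
    scales.  With ``noise_scale=0`` every response is an exact function of
    its design cell.
    """
    population = population or study_population(pruned=False)
    model = population.model
    rng = np.random.default_rng(design.seed)

    cells = list(itertools.product(design.pah_levels, design.mp_levels,
                                   design.turbulence_levels))
    rows = [cell for cell in cells for _ in range(design.replicates)]
    df = pd.DataFrame(rows, columns=["pah_activity", "mp", "turbulence_level"])
    n = len(df)
    turb01 = (df["turbulence_level"].astype(str)
              == str(design.turbulence_levels[-1])).astype(float)
    # 0/1 coding (last design level = 1) so the column doubles as the
    # turbulence construct's indicator; the label column keeps readability
    df.insert(2, "turbulence", turb01.astype(int))

    lo, hi = design.turbidity_range
    span = hi - lo
    turbidity = (lo + 0.12 * span
                 + 0.55 * span * turb01.to_numpy()
                 + 0.18 * span * df["mp"].astype(float).to_numpy()
                 + noise_scale * rng.normal(0.0, 0.08 * span, n))
    df["turbidity"] = np.clip(turbidity, lo, hi)

    def _z(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    scores: dict[str, np.ndarray] = {
        "pahs": _z(df["pah_activity"].to_numpy()),
        "microplastics": _z(df["mp"].to_numpy()),
        "turbulence": _z(turb01.to_numpy()),
        "sediment_resuspension": _z(df["turbidity"].to_numpy()),
    }
    _, residual = _construct_system(population.path_values, model,
                                    population.exo_correlations)
    for construct in model.topological_order():
        if construct in scores:
            continue
        preds = model.predecessors(construct)
        eta = sum(population.path_values[(p, construct)] * scores[p] for p in preds)
        eta = eta + noise_scale * np.sqrt(residual[construct]) * rng.standard_normal(n)
        scores[construct] = np.asarray(eta)

    design_cols = {"pah_activity", "mp", "turbulence", "turbidity"}
    for construct, block in model.blocks.items():
        for ind in block:
            if ind in design_cols:
                continue
            lam = population.loading_values[ind]
            z = lam * scores[construct] + noise_scale * np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal(n)
            loc, scale = RESPONSE_SCALES.get(ind, (0.0, 1.0))
            df[ind] = loc + scale * z

    photometry = [c for c in PHOTOMETRY_COLUMNS if c in df.columns]
    slots = [(i, c) for c in photometry for i in range(n)]
    if design.n_missing > len(slots):
        raise InvalidParametersError(
            f"n_missing={design.n_missing} exceeds the {len(slots)} photometry cells"
        )
    if design.n_missing:
        chosen = rng.choice(len(slots), size=design.n_missing, replace=False)
        for k in chosen:
            i, c = slots[k]
            df.loc[i, c] = np.nan
    return df


# ---------------------------------------------------------------------------
# CSV I/O with provenance sidecar
# ---------------------------------------------------------------------------


def write_sample_table(df: pd.DataFrame, path: str, meta: dict | None = None) -> None:
    """Write a sample table as headered CSV (missing cells empty) plus a
    ``<path>.meta.json`` provenance sidecar."""
    df.to_csv(path, index=False, na_rep="")
    sidecar = dict(meta or {})
    sidecar.setdefault("n_rows", int(len(df)))
    sidecar.setdefault("columns", list(df.columns))
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def read_sample_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path)
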