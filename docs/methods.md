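# Methods

This note documents the models implemented in `multistress`, the choices
made where the methodology was genuinely open, and what the synthetic data
can and cannot establish.

## Chemical-activity dosimetry

Per congener, the freely dissolved concentration is `C_free = C_algae /
K_OC` and the activity `a = C_free / S_L`; the mixture total is the sum of
congener activities, which is the standard additivity assumption for
baseline (narcotic) toxicity of hydrophobic organics. Activities above 1
indicate super-saturation; they are flagged rather than rejected because
the dosimetry itself remains well defined there. `K_OC` and `S_L` are
accepted on natural scale, with `log_koc`/`log_sl` columns converted at
parse time since literature tables mix both conventions. No temperature
correction, sorption kinetics or structure-based estimation is attempted.

## Preprocessing

**Box–Cox.** The exponent is estimated per column by profile maximum
likelihood: a 61-point grid on [−3, 3] followed by bounded scalar
refinement to 1e−4. The profile-likelihood maximizer is invariant to
positive rescaling of the data, which the tests exploit. Responses must be
strictly positive; the transform is continuous in λ at 0.

**EM imputation.** Missing photometry cells (Fv/Fm, Y(II), NPQ in the
reference design) are completed by a single EM pass under a joint
multivariate normal over *all* numeric columns, so complete responses act
as auxiliary variables and contribute their full multinormal information.
The E-step uses conditional means and accumulates conditional covariances;
the M-step uses maximum-likelihood (denominator n) moments. The
observed-data log-likelihood is asserted non-decreasing at every
iteration; convergence is the largest parameter change < 1e−6 (default),
capped at 500 iterations with a warning on non-convergence. A single
completed table (conditional means) is returned — no multiple imputation —
and observed cells are preserved bit-exactly. This matches a
missing-completely-at-random dropout mechanism, which is also what the
experiment-mode generator produces.

**Standardization** is the z-score with the n−1 denominator, used
consistently everywhere (PLS scores, loadings, path coefficients).

## GLM screening and RESI

Each response is fitted with a normal-error GLM (identity or log link)
through iteratively reweighted least squares; Wald statistics are
`(coef/se)²` against χ²₁, and deviance/Pearson χ² are reported for fit
checking. Candidate two-way interactions (MP × PAH activity, MP ×
turbidity, PAH activity × turbidity) are pruned in a single pass: the full
model is fitted once and every interaction with group-Wald p ≥ 0.05 is
dropped simultaneously — the screening is not stepwise. Categorical
stressors are treatment-coded against their reference level (low
turbulence, MP absent).

The robust effect size index for a dropped term set with Wald χ² `T²` on
`m` df at sample size `n` is `S = sqrt(max(0, (T² − m)/n))`, with
conversions `f² = S²`, `d = 2S` and half-open magnitude bands [0, 0.1)
small, [0.1, 0.25) medium, [0.25, 0.4) large, ≥ 0.4 very large. The
power routine finds the smallest n for which the noncentral-F test of a
single coefficient (numerator df 1, denominator df n − k − 1,
noncentrality f²·n) reaches the requested power; all knobs (α, power,
number of predictors) are exposed rather than hard-wired, because
conventional defaults differ between software packages.

In the default Box–Cox/link configuration, four responses (Chl a+c,
carotenoids, Y(II), ORAC) are transformed and pigments/Fv/Fm/ORAC use the
log link; the pairing is a fixture of the reference design and fully
configurable.

## PLS path modeling

Estimation is the classic alternating scheme for reflective blocks:
equal initial outer weights; construct scores as standardized weighted
indicator sums; inner proxies by the **path** weighting scheme
(predecessors weighted by their joint regression coefficients onto the
focal score, successors by correlations); Mode A outer weights as
indicator–proxy correlations; iterate until the largest weight change is
below 1e−7 (default) or 300 iterations. The path scheme is the de facto
default of mainstream PLS-SEM software; centroid and factor schemes are
available behind a flag for sensitivity analysis. After convergence,
loadings are indicator–score correlations, structural coefficients are
OLS of each endogenous score on its predecessors, and R²/adjusted R²
follow the usual formulas.

Sign indeterminacy is resolved by forcing the largest-|λ| indicator of
every block to load positively. Bootstrap resamples are sign-aligned to
the original loading pattern before aggregation, which prevents the
artificial SE inflation that sign flips would otherwise cause.

**Diagnostics.** AVE is the mean squared loading; Cronbach's α is the
standardized form from the block correlation matrix; ρ_C is composite
reliability `(Σλ)²/((Σλ)² + Σ(1−λ²))`; ρ_A is the Dijkstra–Henseler
formula applied to weights normalized to a unit-variance composite (for a
2-indicator block with equal weights and correlation r it reduces to
2r/(1+r)). Single-indicator constructs report 1 for all reliabilities
with an explicit "not assessable" flag; HTMT pairs involving them fall
back to the plain indicator correlation. SRMR compares the empirical
indicator correlations with a model-implied matrix rebuilt from the
fitted loadings and score correlations using the composite formula below.
f² is `(R²_incl − R²_excl)/(1 − R²_incl)` with bands < 0.02 negligible,
0.02–0.15 weak, 0.15–0.35 moderate, > 0.35 large; VIF comes from
score-level regressions.

**Bootstrap.** Rows are resampled with replacement; every resample refits
the full estimator. Reported per edge and per enumerated indirect/total
effect: bootstrap SE, `t = estimate/SE`, two-sided p from the t
distribution with n−1 df, and bias-corrected-and-accelerated bounds at
the 5% and 95% levels (a 90% interval, configurable) with the
acceleration constant from a leave-one-out jackknife. Two-sided p-values
are a deliberate choice; one-sided conventions exist in some software,
and the difference matters only for marginal paths. Resamples with a
zero-variance indicator are redrawn, counted, and capped at 10% of the
bootstrap size. Degenerate statistics (bootstrap SD below 1e−12) report a
point-mass interval. A Monte-Carlo check in the test suite confirms
88–90% empirical coverage of the 90% BCa interval for a β = 0.5 edge at
n = 200.

**Indirect effects and mediation.** Specific indirect effects are
products of coefficients along each directed path of length ≥ 2
(enumerated over the DAG); the total effect is the direct coefficient
plus their sum, and the identity against the `(I−B)⁻¹ − I` total-effect
matrix is enforced in tests to 1e−10. Mediation classification uses the
bootstrap significances of the direct and total-indirect components:
both significant and same-signed → complementary (partial); opposite
signs → competitive; only indirect → indirect-only (full mediation); only
direct → direct-only; neither → no-effect. The proportion mediated is
|indirect| / (|direct| + |indirect|).

**Indicator screening** removes one indicator per refit — the lowest |λ|
among those with |λ| < 0.5 or bootstrap p > 0.05 — with deterministic
tie-breaking by block order then indicator order, and never empties a
block (the last indicator is retained with a warning).

## Synthetic data

**Population mode** draws from a multivariate normal whose correlation
matrix is implied by the recursive standardized structural system: each
endogenous construct is a linear combination of its predecessors plus an
independent residual sized for unit variance (a residual that would need
negative variance raises an error). Indicators are *composite-consistent*:
within a block, correlations satisfy `S_b λ = (λ'λ) λ`, which makes the
loading-weighted composite have exactly unit variance and correlate λᵢ
with each indicator; across blocks, `corr(xᵢ∈A, xⱼ∈B) = λᵢ·corr(A,B)·λⱼ`.
Under this regime the PLS estimator is consistent for the generating
paths, so parameter recovery at large n is a meaningful correctness test.
Common-factor generation would instead attenuate PLS estimates and make
recovery tolerances meaningless — that is why composites, not factors,
define the population. For equal within-block loadings the
composite-consistency condition has the closed-form solution
`r = (Kλ² − 1)/(K − 1)`; for unequal loadings the linear system in the
off-diagonals is solved exactly when possible (provably impossible for
two unequal loadings) and an invalid-parameters error names the offending
block otherwise.

The default generating system is the eight-construct stressor→response
topology with the full-model standardized path coefficients (turbulence →
sediment resuspension 0.564, microplastics → sediment resuspension 0.382,
sediment resuspension → PAHs 0.099, PAHs → pigments −0.265, turbulence →
pigments −0.442, PAHs → PSII −0.766, pigments → PSII 0.200, antioxidant →
PSII −0.028, PAHs → antioxidant −0.004, sediment resuspension →
antioxidant 0.568, PSII → elemental ratios 0.494, sediment resuspension →
elemental ratios −0.684), loadings 0.9 for multi-indicator blocks and 1.0
for single-indicator constructs, and orthogonal exogenous constructs (the
factorial design makes them orthogonal by construction). Exact indicator
loadings of the original instrument are not recoverable, so 0.9 is a
conventional strong-measurement default; under composite-consistent
generation path recovery does not depend on this choice.

**Experiment mode** reproduces the factorial layout: the
design-controlled constructs (PAHs, microplastics, turbulence) are pinned
to the standardized design columns; turbidity is an increasing function
of turbulence and MP presence plus noise, clipped to 0.8–3.9 NTU, and its
standardization is the sediment-resuspension construct; downstream
constructs follow the structural recursion with Gaussian residuals;
response indicators are loading-weighted scores plus unique noise, placed
on plausible measurement scales (e.g. Chl 6 ± 1 mg g⁻¹, Fv/Fm
0.65 ± 0.06, ORAC 40 ± 8, %C 30 ± 2) chosen so that Box–Cox inputs stay
strictly positive. Weak indicators (NPQ, %C, %N) are generated at loading
0.3 so the 0.5-loading screen removes exactly them, mirroring the
measurement pruning of the reference analysis. Exactly `n_missing` cells
(default 4) are blanked uniformly at random within the photometry
columns — MCAR, matching the EM model. The design columns are binary
while population mode uses continuous Gaussian proxies for the same
constructs; this discrepancy is intentional (it lets the implied-matrix
machinery be exact in population mode) and is why population mode, not
experiment mode, is the parameter-recovery surface.

What passing tests therefore show: the estimator recovers generating
parameters under its own consistency regime, intervals are calibrated,
and every pipeline stage is internally correct. What they do not show:
anything about attenuation under common-factor data, non-normal
indicators, or the behavior of n = 24 inference beyond qualitative
agreement — small-sample path estimates (see the README example) are
visibly noisier than their population values.

## Problem sizes and numerical conventions

Recovery checks use 10 replicates of n = 5000 (Monte-Carlo SE of the mean
recovered coefficient ≈ 0.004, comfortably inside the ±0.05 tolerance);
the interval-coverage check uses 500 replicates × 999 resamples at
n = 200; the type-I-error check uses 2000 null datasets at the reference
n = 24. Matrix PSD checks tolerate eigenvalues ≥ −1e−8; PLS convergence
is 1e−7 on weights; EM convergence 1e−6 on parameters; degenerate inputs
(constant columns, emptied blocks, cyclic path specifications,
explosive implied variances) raise typed errors naming the offender.

## Known limitations

Mode A reflective measurement only — no formative blocks, no consistent-
PLS correction, no moderation constructs or multi-group analysis; single
imputation only; GLMs are Gaussian-family only (no quasi-likelihood or
random effects); mediation significance reuses the path bootstrap rather
than a separate product-distribution method. The mediation sign rule
classifies same-signed significant direct and indirect components as
complementary; datasets whose direct and indirect estimates share a sign
can therefore never be labeled competitive, whatever their provenance.
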