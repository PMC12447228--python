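"""GLM screening: fitting oracles, interaction pruning, RESI, power."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from multistress.glm import (
    GLMSpec,
    classify_s,
    fit_glm,
    prune_interactions,
    required_sample_size,
    resi_from_wald,
    resi_s,
    run_glm_battery,
)


def _table(rng, n=200, k=2):
    return pd.DataFrame(rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)])


class TestFitGLM:
    def test_exact_linear_data_zero_deviance(self, rng):
        df = _table(rng, 50, 1)
        df["y"] = 1.0 + 2.0 * df["x0"]
        res = fit_glm(df, GLMSpec(response="y", predictors=("x0",)))
        assert res.params["intercept"] == pytest.approx(1.0, abs=1e-8)
        assert res.params["x0"] == pytest.approx(2.0, abs=1e-8)
        assert res.deviance == pytest.approx(0.0, abs=1e-12)

    def test_identity_link_matches_ols_closed_form(self, rng):
        """IRLS with identity link equals the least-squares pseudoinverse
        solution on 50 random instances."""
        for _ in range(50):
            n = int(rng.integers(20, 60))
            df = _table(rng, n, 3)
            df["y"] = rng.normal(size=n) + df["x0"] - 0.5 * df["x2"]
            res = fit_glm(df, GLMSpec(response="y", predictors=("x0", "x1", "x2")))
            X = np.column_stack([np.ones(n), df[["x0", "x1", "x2"]].to_numpy()])
            beta = np.linalg.pinv(X) @ df["y"].to_numpy()
            assert np.max(np.abs(res.params.to_numpy() - beta)) < 1e-8

    def test_log_link_generative_recovery(self, rng):
        n = 10_000
        df = _table(rng, n, 1)
        df["y"] = np.exp(0.5 + 0.3 * df["x0"]) + rng.normal(0, 0.1, n)
        res = fit_glm(df, GLMSpec(response="y", predictors=("x0",), link="log"))
        assert res.params["intercept"] == pytest.approx(0.5, abs=0.05)
        assert res.params["x0"] == pytest.approx(0.3, abs=0.05)

    def test_wald_is_squared_z_with_chi2_pvalue(self, rng):
        df = _table(rng, 40, 1)
        df["y"] = df["x0"] + rng.normal(size=40)
        res = fit_glm(df, GLMSpec(response="y", predictors=("x0",)))
        coef, se, wald, p = res.estimates["x0"]
        assert wald == pytest.approx((coef / se) ** 2, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(wald, 1), rel=1e-12)
        assert res.df_resid == 40 - 2

    def test_rank_deficient_design_rejected(self, rng):
        df = _table(rng, 30, 1)
        df["dup"] = df["x0"]
        df["y"] = rng.normal(size=30)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_glm(df, GLMSpec(response="y", predictors=("x0", "dup")))

    def test_categorical_treatment_coding(self, rng):
        df = pd.DataFrame({
            "g": ["low"] * 10 + ["high"] * 10,
            "y": np.r_[rng.normal(0, 0.1, 10), rng.normal(1, 0.1, 10)],
        })
        res = fit_glm(df, GLMSpec(response="y", predictors=("g",),
                                  categorical={"g": "low"}))
        assert "g(high)" in res.terms
        assert res.params["g(high)"] == pytest.approx(
            df.y[10:].mean() - df.y[:10].mean(), abs=1e-8)


class TestPruneInteractions:
    def test_null_interaction_removed(self, rng):
        n = 10_000
        df = _table(rng, n, 2)
        df["y"] = df["x0"] + df["x1"] + rng.normal(size=n)
        spec = GLMSpec(response="y", predictors=("x0", "x1"),
                       interactions=(("x0", "x1"),))
        assert prune_interactions(df, spec).interactions == ()

    def test_strong_interaction_retained(self, rng):
        n = 10_000
        df = _table(rng, n, 2)
        df["y"] = df["x0"] + 0.5 * df["x0"] * df["x1"] + rng.normal(size=n)
        spec = GLMSpec(response="y", predictors=("x0", "x1"),
                       interactions=(("x0", "x1"),))
        assert prune_interactions(df, spec).interactions == (("x0", "x1"),)

    def test_no_candidates_unchanged(self, rng):
        df = _table(rng, 50, 2)
        df["y"] = rng.normal(size=50)
        spec = GLMSpec(response="y", predictors=("x0", "x1"))
        assert prune_interactions(df, spec) is spec


class TestResi:
    def test_null_statistic_gives_zero(self):
        assert resi_from_wald(t2=1.0, m=1, n=24).s_beta == 0.0

    def test_hand_arithmetic(self):
        est = resi_from_wald(t2=9.0, m=1, n=24)
        assert est.s_beta == pytest.approx(np.sqrt(8 / 24), abs=1e-12)
        assert est.s_beta == pytest.approx(0.5774, abs=1e-4)

    def test_conversions_are_definitional(self):
        est = resi_from_wald(t2=1 + 24 * 0.25, m=1, n=24)  # S = 0.5 exactly
        assert est.s_beta == pytest.approx(0.5, abs=1e-12)
        assert est.f_squared == pytest.approx(0.25, abs=1e-12)
        assert est.cohens_d == pytest.approx(1.0, abs=1e-12)

    def test_full_vs_reduced_model_comparison(self, rng):
        n = 500
        df = _table(rng, n, 2)
        df["y"] = 0.5 * df["x0"] + rng.normal(size=n)
        full = fit_glm(df, GLMSpec(response="y", predictors=("x0", "x1")))
        reduced = fit_glm(df, GLMSpec(response="y", predictors=("x1",)))
        est = resi_s(full, reduced)
        coef, se, wald, _ = full.estimates["x0"]
        assert est.s_beta == pytest.approx(np.sqrt(max(0, (wald - 1) / n)), abs=1e-10)
        with pytest.raises(ValueError, match="nested"):
            resi_s(reduced, full)

    def test_invariant_to_predictor_rescaling(self, rng):
        n = 300
        df = _table(rng, n, 2)
        df["y"] = 0.4 * df["x0"] + rng.normal(size=n)
        scaled = df.assign(x0=df["x0"] * 123.4)
        spec_full = GLMSpec(response="y", predictors=("x0", "x1"))
        spec_red = GLMSpec(response="y", predictors=("x1",))
        a = resi_s(fit_glm(df, spec_full), fit_glm(df, spec_red)).s_beta
        b = resi_s(fit_glm(scaled, spec_full), fit_glm(scaled, spec_red)).s_beta
        assert a == pytest.approx(b, rel=1e-8)


class TestClassifyS:
    @pytest.mark.parametrize("s, label", [
        (0.05, "small"), (0.1, "medium"), (0.24, "medium"),
        (0.251, "large"), (0.399, "large"), (0.4, "very large"),
        (0.969, "very large"), (0.0, "small"),
    ])
    def test_bands(self, s, label):
        assert classify_s(s) == label

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_s(-0.1)


class TestRequiredSampleSize:
    def test_matches_grid_oracle(self):
        """Binary search equals an exhaustive scan of attained power."""
        f2, alpha, power, k = 0.35, 0.05, 0.80, 1

        def attained(n):
            df2 = n - k - 1
            crit = stats.f.isf(alpha, 1, df2)
            return stats.ncf.sf(crit, 1, df2, f2 * n)

        oracle = next(n for n in range(k + 2, 500) if attained(n) >= power)
        assert required_sample_size(f2, alpha, power, k) == oracle

    def test_huge_effect_approaches_minimum_df(self):
        assert required_sample_size(100.0, 0.05, 0.80, 1) <= 4

    def test_monotone_in_effect_size(self):
        grid = [0.05, 0.1, 0.2, 0.35, 0.8]
        ns = [required_sample_size(f2, 0.05, 0.8, 1) for f2 in grid]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            required_sample_size(0.0)
        with pytest.raises(ValueError):
            required_sample_size(0.3, alpha=1.5)


def test_battery_report_schema(rng):
    from multistress.datasets import ExperimentDesign, sample_experiment, study_population
    from multistress.preprocess import em_impute

    df = sample_experiment(ExperimentDesign(seed=5), study_population(pruned=False))
    completed = em_impute(df).completed
    report = run_glm_battery(completed)
    assert set(report.columns) == {"response", "predictor", "link", "estimate",
                                   "se", "wald", "p", "s_beta"}
    assert set(report["response"]) == {"chl_a_c", "carotenoids", "fv_fm", "y_ii",
                                       "npq", "orac", "pct_c", "pct_h", "pct_n",
                                       "cn_ratio"}
    # S_beta attached exactly to significant rows
    sig = report["p"] < 0.05
    assert report.loc[sig, "s_beta"].notna().all()
    assert report.loc[~sig, "s_beta"].isna().all()
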