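"""PLS path modeling: estimation oracles, diagnostics, bootstrap, mediation."""

import numpy as np
import pandas as pd
import pytest

from multistress.datasets import (
    PopulationModel,
    implied_construct_correlations,
    sample_population,
    study_population,
)
from multistress.model_spec import SemModel
from multistress.pls import (
    PLSPathModel,
    enumerate_indirect,
    prune_indicators,
)

from conftest import (
    oracle_total_effects,
    random_dag_model,
    sequential_ols_paths,
)


def _single_indicator_data(rng, model, values, n=200):
    pop = PopulationModel(model=model, path_values=values, n=n,
                          seed=int(rng.integers(2**31)))
    return sample_population(pop)


class TestEstimator:
    def test_two_construct_beta_equals_correlation(self, rng):
        m = SemModel(blocks={"a": ["x"], "b": ["y"]}, paths=(("a", "b"),))
        df = _single_indicator_data(rng, m, {("a", "b"): 0.6}, n=300)
        res = PLSPathModel(df, m).fit()
        r = float(np.corrcoef(df["x"], df["y"])[0, 1])
        assert res.path_coefficients[("a", "b")] == pytest.approx(r, abs=1e-10)

    def test_single_indicator_equals_sequential_ols(self, rng):
        """On single-indicator models PLS collapses to path analysis:
        standardized sequential OLS, checked on 50 random DAGs."""
        for _ in range(50):
            model, values = random_dag_model(rng, max_nodes=5)
            df = _single_indicator_data(rng, model, values, n=200)
            res = PLSPathModel(df, model).fit()
            oracle = sequential_ols_paths(df, model)
            for edge, beta in oracle.items():
                assert res.path_coefficients[edge] == pytest.approx(beta, abs=1e-10)

    def test_duplicated_indicators_get_equal_weights_unit_loadings(self, rng):
        m = SemModel(blocks={"a": ["x1", "x2"], "b": ["y"]}, paths=(("a", "b"),))
        base = rng.normal(size=120)
        df = pd.DataFrame({"x1": base, "x2": base.copy(),
                           "y": 0.5 * base + rng.normal(size=120)})
        res = PLSPathModel(df, m).fit()
        assert res.weights["x1"] == pytest.approx(res.weights["x2"], abs=1e-10)
        assert res.loadings["x1"] == pytest.approx(1.0, abs=1e-10)
        assert res.loadings["x2"] == pytest.approx(1.0, abs=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        pop = study_population(n=300, seed=13)
        df = sample_population(pop)
        res_a = PLSPathModel(df, pop.model).fit()
        rescaled = df.copy()
        rescaled["fv_fm"] = 100.0 * rescaled["fv_fm"] - 7.0
        rescaled["turbidity"] = 0.01 * rescaled["turbidity"] + 3.0
        res_b = PLSPathModel(rescaled, pop.model).fit()
        for edge, beta in res_a.path_coefficients.items():
            assert res_b.path_coefficients[edge] == pytest.approx(beta, abs=1e-8)
        assert res_b.srmr() == pytest.approx(res_a.srmr(), abs=1e-8)

    def test_adjusted_r2_formula(self, rng):
        pop = study_population(n=200, seed=3)
        df = sample_population(pop)
        res = PLSPathModel(df, pop.model).fit()
        for c, r2 in res.r2.items():
            p = len(pop.model.predecessors(c))
            expect = 1 - (1 - r2) * (200 - 1) / (200 - p - 1)
            assert res.r2_adj[c] == pytest.approx(expect, abs=1e-12)

    def test_missing_cells_rejected(self, rng):
        m = SemModel(blocks={"a": ["x"], "b": ["y"]}, paths=(("a", "b"),))
        df = pd.DataFrame({"x": [1.0, np.nan, 2.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="missing"):
            PLSPathModel(df, m)


class TestDiagnostics:
    def test_saturated_single_indicator_model_has_zero_srmr(self, rng):
        # fully connected DAG over 3 constructs is just-identified
        m = SemModel(
            blocks={"a": ["x"], "b": ["y"], "c": ["z"]},
            paths=(("a", "b"), ("a", "c"), ("b", "c")),
        )
        df = _single_indicator_data(
            rng, m, {("a", "b"): 0.4, ("a", "c"): 0.2, ("b", "c"): 0.3}, n=150)
        res = PLSPathModel(df, m).fit()
        assert res.srmr() == pytest.approx(0.0, abs=1e-10)

    def test_srmr_small_on_well_specified_data(self):
        pop = study_population(n=5000, seed=21)
        res = PLSPathModel(sample_population(pop), pop.model).fit()
        assert res.srmr() < 0.03

    def test_identical_indicator_block_reliabilities_are_one(self, rng):
        m = SemModel(blocks={"a": ["x1", "x2", "x3"], "b": ["y"]},
                     paths=(("a", "b"),))
        base = rng.normal(size=100)
        df = pd.DataFrame({"x1": base, "x2": base.copy(), "x3": base.copy(),
                           "y": rng.normal(size=100)})
        outer = PLSPathModel(df, m).fit().outer_assessment()
        for metric in ("ave", "alpha", "rho_a", "rho_c"):
            assert outer.loc["a", metric] == pytest.approx(1.0, abs=1e-8)

    def test_single_indicator_constructs_flagged_not_assessable(self, rng):
        pop = study_population(n=200, seed=2)
        outer = PLSPathModel(sample_population(pop), pop.model).fit().outer_assessment()
        assert not outer.loc["pahs", "assessable"]
        assert outer.loc["pahs", "ave"] == 1.0
        assert outer.loc["pigments", "assessable"]

    def test_vif_hand_cases(self, rng):
        pop = study_population(n=500, seed=6)
        res = PLSPathModel(sample_population(pop), pop.model).fit()
        lone = res.vif("pahs")  # single predecessor
        assert lone == {"sediment_resuspension": 1.0}
        multi = res.vif("psii_performance")
        C = res.scores[["pigments", "pahs", "antioxidant_capacity"]].corr().to_numpy()
        for i, p in enumerate(["pigments", "pahs", "antioxidant_capacity"]):
            rest = [j for j in range(3) if j != i]
            r2 = C[rest, i] @ np.linalg.solve(C[np.ix_(rest, rest)], C[rest, i])
            assert multi[p] == pytest.approx(1 / (1 - r2), rel=1e-8)

    def test_f2_matches_r2_decomposition(self, rng):
        pop = study_population(n=1000, seed=9)
        res = PLSPathModel(sample_population(pop), pop.model).fit()
        f2 = res.f2()
        assert set(f2) == set(pop.model.paths)
        assert all(v >= 0 for v in f2.values())
        # lone-predictor edge: f2 = R2/(1-R2)
        r2 = res.r2["pahs"]
        assert f2[("sediment_resuspension", "pahs")] == pytest.approx(
            r2 / (1 - r2), rel=1e-10)

    def test_htmt_matrix_is_symmetric_with_unit_diagonal(self):
        pop = study_population(n=300, seed=4)
        H = PLSPathModel(sample_population(pop), pop.model).fit().htmt_matrix()
        assert np.allclose(H, H.T)
        assert np.allclose(np.diag(H), 1.0)
        assert (H.to_numpy() >= 0).all()


class TestIndirectEffects:
    def test_chain_single_product(self):
        m = SemModel(blocks={"a": ["x"], "b": ["y"], "c": ["z"]},
                     paths=(("a", "b"), ("b", "c")))
        out = enumerate_indirect({("a", "b"): 0.5, ("b", "c"): 0.4}, m, "a", "c")
        assert out == [(("a", "b", "c"), pytest.approx(0.2))]

    def test_study_mediated_product(self, chain_model):
        vals = {("pahs", "pigments"): -0.265, ("pigments", "psii"): 0.200,
                ("pahs", "psii"): -0.766}
        out = enumerate_indirect(vals, chain_model, "pahs", "psii")
        assert len(out) == 1
        assert out[0][1] == pytest.approx(-0.053, abs=1e-12)

    def test_totals_match_matrix_oracle(self, rng):
        """Direct + enumerated indirect equals (I-B)^-1 - I on 100 random
        DAGs."""
        for _ in range(100):
            model, values = random_dag_model(rng, max_nodes=6)
            T = oracle_total_effects(model, values)
            names = model.constructs
            for i, s in enumerate(names):
                for j, t in enumerate(names):
                    if s == t:
                        continue
                    total = values.get((s, t), 0.0) + sum(
                        v for _, v in enumerate_indirect(values, model, s, t))
                    assert total == pytest.approx(T[j, i], abs=1e-10)


class TestBootstrap:
    def test_seeded_bit_reproducibility(self):
        pop = study_population(n=60, seed=17)
        res = PLSPathModel(sample_population(pop), pop.model).fit()
        a = res.bootstrap(n_boot=50, seed=5, indirect_pairs=[])
        b = res.bootstrap(n_boot=50, seed=5, indirect_pairs=[])
        assert a.per_edge == b.per_edge
        assert a.loading_p == b.loading_p

    def test_zero_noise_chain_degenerate_interval(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": 2.0 * x})  # perfectly collinear
        m = SemModel(blocks={"a": ["x"], "b": ["y"]}, paths=(("a", "b"),))
        res = PLSPathModel(df, m).fit()
        boot = res.bootstrap(n_boot=100, seed=1, indirect_pairs=[])
        st = boot.per_edge[("a", "b")]
        assert st["se"] < 1e-10
        assert st["ci_low"] == st["ci_high"] == pytest.approx(1.0, abs=1e-12)

    def test_interval_brackets_estimate_and_t_definition(self):
        pop = study_population(n=120, seed=23)
        res = PLSPathModel(sample_population(pop), pop.model).fit()
        boot = res.bootstrap(n_boot=300, seed=2, indirect_pairs=[])
        for edge, st in boot.per_edge.items():
            assert st["t"] == pytest.approx(st["estimate"] / st["se"], rel=1e-10)
            if f"BCa interval excludes the point estimate for {edge}" not in boot.flags:
                assert st["ci_low"] <= st["estimate"] <= st["ci_high"]


class TestMediation:
    @staticmethod
    def _fake_inference(res, pvals):
        boot = res.bootstrap(n_boot=60, seed=3,
                             indirect_pairs=[("a", "c")], jackknife=False)
        for label, p in pvals.items():
            entry = boot.per_edge.get(label) or boot.per_indirect.get(label)
            entry["p"] = p
        return boot

    @pytest.fixture
    def fitted_chain(self, rng):
        m = SemModel(blocks={"a": ["x"], "b": ["y"], "c": ["z"]},
                     paths=(("a", "b"), ("b", "c"), ("a", "c")))
        vals = {("a", "b"): 0.5, ("b", "c"): 0.4, ("a", "c"): 0.3}
        df = _single_indicator_data(rng, m, vals, n=400)
        return PLSPathModel(df, m).fit()

    def test_complementary_when_same_sign_and_both_significant(self, fitted_chain):
        boot = self._fake_inference(fitted_chain, {
            ("a", "c"): 0.001, "total_indirect: a -> c": 0.001})
        med = fitted_chain.mediation("a", "c", inference=boot)
        assert med.classification == "complementary"
        expect = abs(med.total_indirect) / (abs(med.direct) + abs(med.total_indirect))
        assert med.proportion_mediated == pytest.approx(expect, abs=1e-12)
        assert med.total_effect == pytest.approx(med.direct + med.total_indirect,
                                                 abs=1e-10)

    def test_indirect_only_is_full_mediation(self, fitted_chain):
        boot = self._fake_inference(fitted_chain, {
            ("a", "c"): 0.8, "total_indirect: a -> c": 0.001})
        assert fitted_chain.mediation("a", "c", inference=boot).classification \
            == "indirect-only"

    def test_competitive_when_signs_oppose(self, rng):
        m = SemModel(blocks={"a": ["x"], "b": ["y"], "c": ["z"]},
                     paths=(("a", "b"), ("b", "c"), ("a", "c")))
        vals = {("a", "b"): 0.5, ("b", "c"): -0.4, ("a", "c"): 0.5}
        df = _single_indicator_data(rng, m, vals, n=2000)
        res = PLSPathModel(df, m).fit()
        boot = self._fake_inference(res, {
            ("a", "c"): 0.001, "total_indirect: a -> c": 0.001})
        assert res.mediation("a", "c", inference=boot).classification == "competitive"

    def test_no_effect_when_nothing_significant(self, fitted_chain):
        boot = self._fake_inference(fitted_chain, {
            ("a", "c"): 0.9, "total_indirect: a -> c": 0.9})
        assert fitted_chain.mediation("a", "c", inference=boot).classification \
            == "no-effect"


class TestPruneIndicators:
    def test_well_specified_model_unchanged(self):
        pop = study_population(pruned=True, n=500, seed=31)
        df = sample_population(pop)
        pruned = prune_indicators(df, pop.model, n_boot=100, seed=1)
        assert pruned.blocks == pop.model.blocks

    def test_single_weak_indicator_removed(self):
        m = SemModel(blocks={"a": ["x1", "x2", "x3"], "b": ["y"]},
                     paths=(("a", "b"),))
        pop = PopulationModel(
            model=m, path_values={("a", "b"): 0.5},
            loading_values={"x1": 0.9, "x2": 0.9, "x3": 0.2, "y": 1.0},
            n=500, seed=7)
        df = sample_population(pop)
        pruned = prune_indicators(df, m, n_boot=100, seed=1)
        assert pruned.blocks["a"] == ["x1", "x2"]

    def test_study_weak_indicators_all_removed(self):
        """NPQ-, %C- and %N-like indicators generated at loading 0.3 are
        screened out, reproducing the study's measurement pruning."""
        pop = study_population(pruned=False, n=500, seed=11)
        df = sample_population(pop)
        pruned = prune_indicators(df, pop.model, n_boot=100, seed=1)
        assert pruned.blocks["psii_performance"] == ["fv_fm", "y_ii"]
        assert pruned.blocks["elemental_ratios"] == ["pct_h", "cn_ratio"]

    def test_last_indicator_never_removed(self, rng):
        m = SemModel(blocks={"a": ["x"], "b": ["y"]}, paths=(("a", "b"),))
        df = pd.DataFrame(rng.normal(size=(80, 2)), columns=["x", "y"])
        with pytest.warns(UserWarning, match="retained"):
            pruned = prune_indicators(df, m, loading_cutoff=1.1, n_boot=0)
        assert pruned.blocks == m.blocks


def test_parameter_recovery_single_replicate():
    """Fitted paths on composite-consistent data (n = 5000) sit close to
    the generating coefficients."""
    pop = study_population(pruned=True, n=5000, seed=101)
    res = PLSPathModel(sample_population(pop), pop.model).fit()
    for edge, beta in pop.path_values.items():
        assert res.path_coefficients[edge] == pytest.approx(beta, abs=0.06), edge
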