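"""REML engine and the two-step trial analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as stn

from ryegs.mixed import VarianceComponentsModel
from ryegs.pheno import (VarianceComponents, heritability, repeatability,
                         ge_ratio, oneway_anova_components,
                         twoway_anova_components, step1_blues, step2_fit)


class TestREMLEngine:
    def test_matches_oneway_anova_closed_form(self):
        # oracle: balanced one-way random layout has closed-form REML
        # sigma2_between = (MSB - MSW)/n, sigma2_within = MSW
        rng = np.random.default_rng(42)
        g, n = 10, 4
        y = (np.repeat(rng.normal(0, 1.5, g), n) + rng.normal(0, 1.0, g * n))
        res = VarianceComponentsModel(
            y, None, {"group": np.repeat(np.arange(g), n)}).fit()
        between, within = oneway_anova_components(y.reshape(g, n))
        assert res.vcomp["group"] == pytest.approx(between, rel=1e-6)
        assert res.vcomp["residual"] == pytest.approx(within, rel=1e-6)

    def test_constant_data_gives_zero_variances(self):
        res = VarianceComponentsModel(
            np.full(12, 7.5), None, {"g": np.arange(12) % 3}).fit()
        assert res.vcomp["g"] == pytest.approx(0.0, abs=1e-12)
        assert res.vcomp["residual"] == pytest.approx(0.0, abs=1e-12)
        assert res.fe_params[0] == pytest.approx(7.5)

    def test_loglik_nondecreasing_over_accepted_iterations(self):
        rng = np.random.default_rng(3)
        y = np.repeat(rng.normal(0, 1, 15), 3) + rng.normal(0, 2, 45)
        res = VarianceComponentsModel(
            y, None, {"g": np.repeat(np.arange(15), 3)}).fit()
        diffs = np.diff(res.trace)
        assert (diffs > -1e-8).all()

    def test_two_crossed_components_match_twoway_anova(self):
        rng = np.random.default_rng(8)
        g, e = 25, 6
        Y = (rng.normal(0, 2, g)[:, None] + rng.normal(0, 1.5, e)[None, :]
             + rng.normal(0, 1, (g, e)))
        long = pd.DataFrame({
            "v": Y.ravel(),
            "g": np.repeat(np.arange(g), e),
            "e": np.tile(np.arange(e), g)})
        res = VarianceComponentsModel(
            long["v"].to_numpy(), None,
            {"g": long["g"].to_numpy(), "e": long["e"].to_numpy()}).fit()
        comps = twoway_anova_components(Y)
        assert res.vcomp["g"] == pytest.approx(comps["genotype"], rel=1e-5)
        assert res.vcomp["e"] == pytest.approx(comps["environment"], rel=1e-5)
        assert res.vcomp["residual"] == pytest.approx(comps["residual"], rel=1e-5)

    def test_single_level_random_term_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            VarianceComponentsModel(np.ones(4), None, {"g": np.zeros(4)})


class TestStep1:
    @staticmethod
    def _mini_trial(noise_sd: float, seed: int = 0) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        genos = [f"g{i}" for i in range(12)]
        rows = []
        for rep in (1, 2):
            for i, g in enumerate(genos):
                rows.append(("E1", g, rep, 1, 10.0 + i + rng.normal(0, noise_sd)))
        df = pd.DataFrame(rows, columns=["environment", "genotype", "rep",
                                         "block", "value"])
        df["trait"] = "t"
        return df

    def test_noiseless_blue_equals_plot_value(self):
        trial = self._mini_trial(0.0)
        res = step1_blues(trial, "E1")
        expect = trial.groupby("genotype")["value"].first()
        pd.testing.assert_series_equal(res.blues.sort_index(),
                                       expect.sort_index(),
                                       check_names=False)

    def test_blue_is_two_plot_mean_without_block_variance(self):
        # balanced data, no block structure: GLS reduces to the plain mean
        trial = self._mini_trial(1.0, seed=5)
        res = step1_blues(trial, "E1")
        expect = trial.groupby("genotype")["value"].mean()
        np.testing.assert_allclose(res.blues.sort_index(), expect.sort_index(),
                                   rtol=1e-8)

    def test_blues_match_direct_gls_at_fitted_variances(self, yield_study):
        trial = yield_study["sim"].trial
        env = trial["environment"].iloc[0]
        res = step1_blues(trial, env)
        d = trial[trial["environment"] == env]
        # independent GLS: rebuild V from the fitted variances and solve
        genos = np.sort(d["genotype"].unique())
        X = (d["genotype"].to_numpy()[:, None] == genos[None, :]).astype(float)
        V = np.eye(len(d)) * res.vcomp["residual"]
        for term, col in (("rep", d["rep"].astype(str)),
                          ("block", d["rep"].astype(str) + ":" + d["block"].astype(str))):
            if term in res.vcomp:
                Z = pd.get_dummies(col).to_numpy(dtype=float)
                V += res.vcomp[term] * Z @ Z.T
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ d["value"].to_numpy())
        np.testing.assert_allclose(res.blues.to_numpy(), beta, rtol=1e-6)

    def test_single_replication_rejected(self):
        trial = self._mini_trial(1.0)
        trial = trial[trial["rep"] == 1]
        with pytest.raises(ValueError, match="replication"):
            step1_blues(trial, "E1")


class TestStep2:
    def test_identical_blues_give_zero_interaction(self):
        b = pd.DataFrame({"E1": [1.0, 2.0, 3.0], "E2": [1.0, 2.0, 3.0]},
                         index=["g1", "g2", "g3"])
        vc = step2_fit(b, "random")
        assert vc.sigma2_ge == pytest.approx(0.0)
        blue = step2_fit(b, "fixed")
        pd.testing.assert_series_equal(blue, b["E1"], check_names=False)

    def test_single_environment_rejected(self):
        b = pd.DataFrame({"E1": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="single environment|2 environments"):
            step2_fit(b, "random")

    def test_across_env_blue_equals_mean_by_reml_identity(self, yield_study):
        # independent route: the iterative REML/GLS fit on the long table
        # must reproduce the balanced identity BLUE = row mean
        b = yield_study["ana"].blues_by_env.iloc[:40]
        long = b.stack().rename("value").reset_index()
        long.columns = ["genotype", "environment", "value"]
        genos = np.sort(long["genotype"].unique())
        X = (long["genotype"].to_numpy()[:, None] == genos[None, :]).astype(float)
        res = VarianceComponentsModel(
            long["value"].to_numpy(), X,
            {"environment": long["environment"].to_numpy()}).fit()
        np.testing.assert_allclose(res.fe_params,
                                   b.mean(axis=1).loc[genos].to_numpy(),
                                   rtol=1e-6)

    def test_blue_blup_correlation_one_under_balance(self, yield_study):
        b = yield_study["ana"].blues_by_env.iloc[:60]
        long = b.stack().rename("value").reset_index()
        long.columns = ["genotype", "environment", "value"]
        res = VarianceComponentsModel(
            long["value"].to_numpy(), None,
            {"genotype": long["genotype"].to_numpy(),
             "environment": long["environment"].to_numpy()}).fit()
        blues = b.mean(axis=1).loc[np.sort(b.index)]
        blups = res.blup("genotype")
        r = np.corrcoef(blues.to_numpy(), blups)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_component_split_uses_step1_error(self):
        rng = np.random.default_rng(9)
        b = pd.DataFrame(rng.normal(size=(50, 4)),
                         index=[f"g{i}" for i in range(50)],
                         columns=list("WXYZ"))
        err = pd.Series(2.0, index=list("WXYZ"))
        vc = step2_fit(b, "random", error_variances=err, n_rep=2)
        vc_naive = step2_fit(b, "random")
        assert vc.sigma2_e == pytest.approx(2.0)
        assert vc.sigma2_ge == pytest.approx(
            max(vc_naive.sigma2_ge - 1.0, 0.0), rel=1e-9)


class TestAnalyzeTrial:
    def test_repeatability_path_on_small_trial(self, world):
        import ryegs as rg
        from ryegs.pheno import analyze_trial
        arch = rg.TraitArchitecture(trait="t", n_qtl=10, sigma2_g=2.0,
                                    sigma2_e=1.0, sigma2_rep=0.2, n_env=2)
        pop = rg.simulate_f3_population(world["parents"], ("P1", "P2"), 60,
                                        seed=71, label="A")
        sim = rg.simulate_trial([pop], arch, seed=72)
        ana = analyze_trial(sim.trial, compute_repeatability=True)
        assert ana.repeatabilities is not None
        assert ((ana.repeatabilities >= 0) & (ana.repeatabilities <= 1)).all()
        # high signal-to-noise design: repeatability should be substantial
        assert ana.repeatabilities.median() > 0.5


class TestDerivedQuantities:
    @pytest.mark.parametrize("comps,expect", [
        ((3.33, 8.40, 3.48), 0.75),     # grain yield, population A
        ((7.30, 4.03, 2.94), 0.92),     # plant height, population A
        ((3.76, 9.18, 3.72), 0.75),     # grain yield, population B
        ((12.62, 4.02, 2.22), 0.96),    # plant height, population B
    ])
    def test_heritability_reference_values(self, comps, expect):
        vc = VarianceComponents(*comps, n_env=9, n_rep=2)
        assert round(heritability(vc), 2) == expect

    def test_heritability_limits(self):
        vc = VarianceComponents(2.0, 0.0, 0.0, n_env=5, n_rep=2)
        assert heritability(vc) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            heritability(VarianceComponents(0.0, 0.0, 0.0, n_env=1, n_rep=1))

    @given(sg=stn.floats(0.1, 50), sge=stn.floats(0.0, 50),
           se=stn.floats(0.0, 50), ne=stn.integers(1, 20),
           nr=stn.integers(1, 5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_heritability_monotonicity(self, sg, sge, se, ne, nr):
        h = heritability(VarianceComponents(sg, sge, se, n_env=ne, n_rep=nr))
        assert 0.0 <= h <= 1.0
        h_more_env = heritability(
            VarianceComponents(sg, sge, se, n_env=ne + 1, n_rep=nr))
        h_more_ge = heritability(
            VarianceComponents(sg, sge + 1.0, se, n_env=ne, n_rep=nr))
        assert h_more_env >= h - 1e-12
        assert h_more_ge <= h + 1e-12

    @pytest.mark.parametrize("sg,se,nr,expect", [
        (0.0, 1.0, 2, 0.0), (1.0, 0.0, 2, 1.0), (1.0, 2.0, 2, 0.5),
    ])
    def test_repeatability(self, sg, se, nr, expect):
        assert repeatability(sg, se, nr) == pytest.approx(expect)

    @pytest.mark.parametrize("sg,sge,expect", [
        (3.33, 8.40, 0.72), (3.76, 9.18, 0.71),    # grain yield A / B
        (7.30, 4.03, 0.36), (12.62, 4.02, 0.24),   # plant height A / B
        (5.0, 0.0, 0.0),
    ])
    def test_ge_ratio(self, sg, sge, expect):
        vc = VarianceComponents(sg, sge, 1.0, n_env=9, n_rep=2)
        assert round(ge_ratio(vc), 2) == expect
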