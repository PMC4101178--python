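"""Composite interval mapping and marker-assisted selection."""

import numpy as np
import pandas as pd
import pytest

import ryegs as rg
from ryegs.mas import (cim_scan, mas_qtl_predict, sample_neutral_markers,
                       mas_accuracy)


@pytest.fixture(scope="module")
def grid_fixture():
    """20 lines on a hand-made integer-position map (one chromosome)."""
    rng = np.random.default_rng(17)
    rows = [(f"m{i}", 1, 10.0 * i) for i in range(4)]
    gmap = rg.GeneticMap(pd.DataFrame(
        rows, columns=["marker_id", "chromosome", "position_cM"]))
    geno = pd.DataFrame(rng.choice([0.0, 2.0], size=(20, 4)),
                        index=[f"l{i}" for i in range(20)],
                        columns=[r[0] for r in rows])
    y = pd.Series(1.5 * geno["m1"].to_numpy() + rng.normal(0, 1, 20),
                  index=geno.index)
    return geno, y, gmap


class TestScan:
    def test_lod_at_marker_equals_hand_regression(self, grid_fixture):
        # oracle: simple regression RSS ratio computed independently
        geno, y, gmap = grid_fixture
        scan = cim_scan(geno, y, gmap, cofactor_alpha=0.0).scan
        n = len(y)
        yv = y.to_numpy()
        for mid, pos in [("m1", 10.0), ("m2", 20.0)]:
            x = geno[mid].to_numpy()
            rss0 = float(((yv - yv.mean()) ** 2).sum())
            b = np.polyfit(x, yv, 1)
            rss1 = float(((yv - np.polyval(b, x)) ** 2).sum())
            expect = (n / 2.0) * np.log10(rss0 / rss1)
            got = scan.loc[(scan["chromosome"] == 1)
                           & (scan["position_cM"] == pos), "lod"].iloc[0]
            assert got == pytest.approx(expect, rel=1e-9)

    def test_zero_cofactors_reduce_to_simple_interval_mapping(self, grid_fixture):
        # oracle: independent simple-interval-mapping loop with linear
        # flanking interpolation
        geno, y, gmap = grid_fixture
        scan = cim_scan(geno, y, gmap, cofactor_alpha=0.0).scan
        assert cim_scan(geno, y, gmap, cofactor_alpha=0.0).cofactors == []
        n = len(y)
        yv = y.to_numpy()
        pos_m = [10.0 * i for i in range(4)]
        for _, row in scan.iterrows():
            d = row["position_cM"]
            j = int(np.searchsorted(pos_m, d))
            if j == 0:
                x = geno["m0"].to_numpy()
            elif j >= 4:
                x = geno["m3"].to_numpy()
            elif pos_m[j] == d:
                x = geno[f"m{j}"].to_numpy()
            else:
                w = (pos_m[j] - d) / (pos_m[j] - pos_m[j - 1])
                x = w * geno[f"m{j-1}"].to_numpy() \
                    + (1 - w) * geno[f"m{j}"].to_numpy()
            rss0 = float(((yv - yv.mean()) ** 2).sum())
            A = np.column_stack([np.ones(n), x])
            coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
            rss1 = float(((yv - A @ coef) ** 2).sum())
            expect = max(0.0, (n / 2.0) * np.log10(rss0 / rss1))
            assert row["lod"] == pytest.approx(expect, abs=1e-9)

    def test_pure_noise_rarely_detects_qtl(self, world):
        geno = world["pop_a"].genotypes.iloc[:120].astype(float)
        rng = np.random.default_rng(23)
        false_hits = 0
        n_rep = 15
        for _ in range(n_rep):
            y = pd.Series(rng.normal(size=len(geno)), index=geno.index)
            if cim_scan(geno, y, world["gmap"]).n_qtl > 0:
                false_hits += 1
        assert false_hits <= max(1, int(0.05 * n_rep) + 1)

    def test_single_large_qtl_located(self, world):
        pop = world["pop_a"]
        seg3 = [m for m in pop.segregating_markers() if m.startswith("c3")]
        target = seg3[len(seg3) // 2]
        truth = world["gmap"].table.set_index("marker_id").loc[target]
        arch = rg.TraitArchitecture(trait="t", n_qtl=1, sigma2_g=3.0,
                                    sigma2_e=1.0, qtl_markers=[target],
                                    qtl_effects=[2.0], n_env=2)
        sim = rg.simulate_trial([pop], arch, seed=31)
        ana = rg.analyze_trial(sim.trial)
        scan = cim_scan(pop.genotypes.astype(float), ana.blues_across,
                        world["gmap"])
        best = scan.qtl.sort_values("lod").iloc[-1]
        assert best["chromosome"] == truth["chromosome"]
        assert abs(best["position_cM"] - truth["position_cM"]) <= 10.0

    def test_too_few_lines_rejected(self, grid_fixture):
        geno, y, gmap = grid_fixture
        with pytest.raises(ValueError, match="cofactors"):
            cim_scan(geno.iloc[:5], y.iloc[:5], gmap, max_cofactors=10)


class TestPrediction:
    def test_no_leakage_from_test_phenotypes(self, yield_study):
        data = yield_study["data"]["A"]
        y = data.blues_by_env.mean(axis=1)
        train, test = y.index[:176], y.index[176:]
        scan = cim_scan(data.markers.loc[train], y.loc[train], data.gmap)
        p1 = mas_qtl_predict(data.markers.loc[train], y.loc[train],
                             data.markers.loc[test], y.loc[test],
                             scan, data.gmap)
        shuffled = pd.Series(np.random.default_rng(1).permutation(
            y.loc[test].to_numpy()), index=test)
        p2 = mas_qtl_predict(data.markers.loc[train], y.loc[train],
                             data.markers.loc[test], shuffled,
                             scan, data.gmap)
        pd.testing.assert_series_equal(p1.predicted, p2.predicted)
        assert p1.r2_cv != pytest.approx(p2.r2_cv)

    def test_zero_qtl_gives_flagged_constant_prediction(self, grid_fixture):
        geno, y, gmap = grid_fixture
        noise = pd.Series(np.random.default_rng(3).normal(size=20),
                          index=geno.index)
        scan = cim_scan(geno, noise, gmap, lod_threshold=50.0)
        assert scan.n_qtl == 0
        out = mas_qtl_predict(geno, noise, geno, noise, scan, gmap)
        assert out.degenerate and out.r2_cv == 0.0
        assert out.predicted.nunique() == 1

    def test_perfect_marker_explains_test_variance(self, world):
        pop = world["pop_a"]
        target = pop.segregating_markers()[10]
        arch = rg.TraitArchitecture(trait="t", n_qtl=1, sigma2_g=2.0,
                                    sigma2_e=0.0, qtl_markers=[target],
                                    qtl_effects=[1.0], n_env=2)
        sim = rg.simulate_trial([pop], arch, seed=37)
        ana = rg.analyze_trial(sim.trial)
        y = ana.blues_across
        train, test = y.index[:150], y.index[150:]
        geno = pop.genotypes.astype(float)
        scan = cim_scan(geno.loc[train], y.loc[train], world["gmap"])
        out = mas_qtl_predict(geno.loc[train], y.loc[train],
                              geno.loc[test], y.loc[test], scan, world["gmap"])
        assert out.r2_cv > 0.95


class TestNeutralMarkers:
    def test_seven_covers_every_linkage_group(self, world):
        ids = sample_neutral_markers(7, world["gmap"], seed=1)
        tab = world["gmap"].table.set_index("marker_id")
        assert sorted(tab.loc[ids, "chromosome"]) == list(range(1, 8))

    def test_counting_contract(self, world):
        assert len(sample_neutral_markers(1, world["gmap"], seed=2)) == 1
        ids = sample_neutral_markers(10, world["gmap"], seed=3)
        assert len(ids) == len(set(ids)) == 10
        tab = world["gmap"].table.set_index("marker_id")
        assert set(tab.loc[ids, "chromosome"]) == set(range(1, 8))

    def test_too_many_rejected(self, world):
        with pytest.raises(ValueError):
            sample_neutral_markers(world["gmap"].n_markers + 1,
                                   world["gmap"], seed=4)


class TestAccuracy:
    @pytest.mark.parametrize("r2,h2,expect", [
        (0.75, 0.75, 1.0), (0.0, 0.5, 0.0),
        (0.25, 0.75, np.sqrt(1 / 3)),
    ])
    def test_values(self, r2, h2, expect):
        assert mas_accuracy(r2, h2) == pytest.approx(expect)

    def test_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            assert mas_accuracy(0.9, 0.5) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mas_accuracy(0.5, 0.0)
        with pytest.raises(ValueError):
            mas_accuracy(1.2, 0.5)
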