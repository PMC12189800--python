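"""Correlation networks, soft threshold, TOM, module detection, eigengenes."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import t as t_dist

from zganet import (
    ExpressionSimConfig,
    adjacency,
    correlation_matrix,
    detect_modules,
    log_cpm,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_threshold,
    simulate_expression,
    tom_similarity,
)
from zganet.coexpression import GREY, ConstantGeneError


def frame(rows, genes, samples=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


@pytest.fixture(scope="module")
def planted():
    counts, samples, truth = simulate_expression(ExpressionSimConfig(seed=1))
    return log_cpm(counts), samples, truth


class TestCorrelation:
    def test_identical_genes(self):
        e = frame([[1, 2, 3, 4], [1, 2, 3, 4]], ["a", "b"])
        assert correlation_matrix(e).loc["a", "b"] == pytest.approx(1.0)

    def test_negated_gene(self):
        e = frame([[1, 2, 3, 4], [-1, -2, -3, -4]], ["a", "b"])
        assert correlation_matrix(e).loc["a", "b"] == pytest.approx(-1.0)

    def test_independent_genes_mean_near_zero(self):
        rng = np.random.default_rng(8)
        e = frame(rng.normal(size=(200, 24)), [f"g{i}" for i in range(200)])
        corr = correlation_matrix(e).to_numpy()
        off = corr[~np.eye(200, dtype=bool)]
        assert abs(off.mean()) < 0.1

    def test_constant_gene_error_names_gene(self):
        e = frame([[1, 1, 1], [1, 2, 3]], ["flat", "ok"])
        with pytest.raises(ConstantGeneError, match="flat"):
            correlation_matrix(e)

    def test_constant_gene_drop_mode(self):
        e = frame([[1, 1, 1], [1, 2, 3], [3, 1, 2]], ["flat", "a", "b"])
        with pytest.warns(UserWarning, match="constant"):
            corr = correlation_matrix(e, on_constant="drop")
        assert "flat" not in corr.index

    def test_needs_three_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(frame([[1, 2], [2, 1]], ["a", "b"]))


class TestSoftThreshold:
    def test_mean_connectivity_monotone_in_beta(self, planted):
        import warnings as w

        expr, _, _ = planted
        with w.catch_warnings():
            w.simplefilter("ignore")
            rep = pick_soft_threshold(expr.iloc[:200])
        ks = rep.mean_connectivity
        assert all(b <= a + 1e-12 for a, b in zip(ks, ks[1:]))

    def test_uncorrelated_data_takes_warning_path(self):
        rng = np.random.default_rng(3)
        e = frame(rng.normal(size=(150, 24)), [f"g{i}" for i in range(150)])
        with pytest.warns(UserWarning, match="no power reached"):
            rep = pick_soft_threshold(e)
        assert not rep.reached_cut
        assert rep.chosen in rep.candidates

    def test_report_reproducible(self, planted):
        expr, _, _ = planted
        sub = expr.iloc[:150]
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            r1 = pick_soft_threshold(sub)
            r2 = pick_soft_threshold(sub)
        assert r1.chosen == r2.chosen
        assert r1.r_squared == pytest.approx(r2.r_squared, nan_ok=True)


class TestAdjacency:
    def test_perfect_correlation_fixed_point(self):
        corr = frame([[1, 1], [1, 1]], ["a", "b"], ["a", "b"])
        for beta in (1, 6, 8):
            assert adjacency(corr, beta).loc["a", "b"] == 1.0

    def test_half_correlation_power_eight(self):
        corr = frame([[1, 0.5], [0.5, 1]], ["a", "b"], ["a", "b"])
        assert adjacency(corr, 8).loc["a", "b"] == pytest.approx(0.00390625)

    def test_beta_one_is_absolute_value(self):
        corr = frame([[1, -0.3], [-0.3, 1]], ["a", "b"], ["a", "b"])
        assert adjacency(corr, 1).loc["a", "b"] == pytest.approx(0.3)

    def test_beta_below_one_rejected(self):
        corr = frame([[1.0]], ["a"], ["a"])
        with pytest.raises(ValueError):
            adjacency(corr, 0.5)


class TestTom:
    def path_adjacency(self):
        # hub gene 1 connected to 2 and 3; 2–3 unconnected
        return frame(
            [[1, 1, 1], [1, 1, 0], [1, 0, 1]], ["g1", "g2", "g3"],
            ["g1", "g2", "g3"],
        )

    def test_path_hub_full_overlap(self):
        tom = tom_similarity(self.path_adjacency())
        # l_12 = 0, min(k) = 1: (0 + 1)/(1 + 1 - 1) = 1
        assert tom.loc["g1", "g2"] == pytest.approx(1.0)

    def test_path_leaves_half_overlap(self):
        tom = tom_similarity(self.path_adjacency())
        # l_23 = 1, a_23 = 0: (1 + 0)/(1 + 1 - 0) = 0.5
        assert tom.loc["g2", "g3"] == pytest.approx(0.5)

    def test_empty_adjacency_gives_zero_overlap(self):
        adj = frame(np.eye(4), list("abcd"), list("abcd"))
        tom = tom_similarity(adj).to_numpy()
        assert np.allclose(tom[~np.eye(4, dtype=bool)], 0.0)

    def test_symmetric_unit_interval(self, planted):
        expr, _, _ = planted
        adj = adjacency(correlation_matrix(expr.iloc[:120]), 8)
        tom = tom_similarity(adj).to_numpy()
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0.0 and tom.max() <= 1.0 + 1e-12


class TestDetectModules:
    def block_tom(self):
        # two blocks of mutually identical genes, orthogonal across blocks
        rng = np.random.default_rng(0)
        p1 = rng.normal(size=12)
        p2 = rng.normal(size=12)
        p2 -= p2.dot(p1) / p1.dot(p1) * p1  # exactly orthogonal
        rows = [p1 + 1e-9 * i for i in range(40)] + [
            p2 + 1e-9 * i for i in range(40)
        ]
        e = frame(rows, [f"g{i:02d}" for i in range(80)])
        return tom_similarity(adjacency(correlation_matrix(e), 8)), e

    def test_two_planted_blocks_exact(self):
        tom, _ = self.block_tom()
        mods = detect_modules(tom, min_module_size=30)
        assert set(mods.unique()) == {"turquoise", "blue"}
        first = mods.iloc[:40]
        second = mods.iloc[40:]
        assert first.nunique() == 1 and second.nunique() == 1

    def test_independent_genes_mostly_grey(self):
        rng = np.random.default_rng(21)
        e = frame(rng.normal(size=(300, 24)), [f"g{i}" for i in range(300)])
        tom = tom_similarity(adjacency(correlation_matrix(e), 8))
        mods = detect_modules(tom)
        assert (mods == GREY).mean() >= 0.9

    def test_min_size_above_total_all_grey(self):
        tom, _ = self.block_tom()
        assert (detect_modules(tom, min_module_size=100) == GREY).all()

    def test_min_size_below_two_rejected(self):
        tom, _ = self.block_tom()
        with pytest.raises(ValueError):
            detect_modules(tom, min_module_size=1)

    def test_invariant_to_gene_order(self, planted):
        expr, _, _ = planted
        tom = tom_similarity(adjacency(correlation_matrix(expr), 8))
        mods = detect_modules(tom)
        perm = list(tom.index[::-1])
        mods_perm = detect_modules(tom.loc[perm, perm])
        assert (mods_perm.loc[mods.index] == mods).all()


class TestEigengenes:
    def test_identical_profile_module(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        e = frame([profile, profile, profile], ["a", "b", "c"])
        mods = pd.Series(["m1"] * 3, index=e.index)
        me = module_eigengenes(e, mods)
        assert me.variance_explained["m1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(me.values.loc["m1"].to_numpy(), z)

    def test_negation_symmetry(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(10, 12))
        e1 = frame(base, [f"g{i}" for i in range(10)])
        e2 = frame(
            np.vstack([base, -base]), [f"g{i}" for i in range(20)]
        )
        mods1 = pd.Series(["m"] * 10, index=e1.index)
        mods2 = pd.Series(["m"] * 20, index=e2.index)
        me1 = module_eigengenes(e1, mods1).values.loc["m"].to_numpy()
        me2 = module_eigengenes(e2, mods2).values.loc["m"].to_numpy()
        assert np.allclose(np.abs(me1), np.abs(me2), atol=1e-8)

    def test_sign_rule_positive_mean_correlation(self, planted):
        expr, _, _ = planted
        tom = tom_similarity(adjacency(correlation_matrix(expr), 8))
        mods = detect_modules(tom)
        me = module_eigengenes(expr, mods)
        for m in me.values.index:
            members = expr.loc[mods[mods == m].index]
            corrs = [
                np.corrcoef(row, me.values.loc[m])[0, 1]
                for row in members.to_numpy()
            ]
            assert np.mean(corrs) >= 0

    def test_planted_eigengene_recovered(self, planted):
        expr, _, truth = planted
        tom = tom_similarity(adjacency(correlation_matrix(expr), 8))
        me = module_eigengenes(expr, detect_modules(tom))
        for m in me.values.index:
            best = max(
                abs(np.corrcoef(me.values.loc[m], truth.eigengenes.loc[pm])[0, 1])
                for pm in truth.eigengenes.index
            )
            assert best >= 0.9

    def test_single_gene_module_rejected(self):
        e = frame([[1, 2, 3], [3, 2, 1]], ["a", "b"])
        mods = pd.Series(["m1", "m2"], index=e.index)
        with pytest.raises(ValueError, match="fewer than 2"):
            module_eigengenes(e, mods)


class TestModuleTrait:
    def samples(self, n_per=4):
        stages = ["8cell"] * n_per + ["16cell"] * n_per + ["32cell"] * n_per
        ids = [f"s{i}" for i in range(len(stages))]
        return pd.DataFrame({"stage": stages}, index=pd.Index(ids, name="sample_id"))

    def test_indicator_eigengene_perfect_correlation(self):
        samples = self.samples()
        ind = (samples["stage"] == "16cell").to_numpy(float)
        me = pd.DataFrame([ind], index=["m"], columns=samples.index)
        res = module_trait_correlation(me, samples)
        row = res[(res.module == "m") & (res.stage == "16cell")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_orthogonal_eigengene_zero_correlation(self):
        samples = self.samples()
        x = np.tile([1.0, -1.0], 6)  # balanced within every stage
        me = pd.DataFrame([x], index=["m"], columns=samples.index)
        res = module_trait_correlation(me, samples)
        for _, row in res.iterrows():
            assert row.r == pytest.approx(0.0, abs=1e-12)
            assert row.p == pytest.approx(1.0, abs=1e-9)

    def test_t_statistic_p_value_formula(self):
        # n = 12, r = 0.9: t = 0.9 sqrt(10/0.19) ~ 6.53, p ~ 6.6e-5
        n, r = 12, 0.9
        t_stat = r * np.sqrt((n - 2) / (1 - r**2))
        p_expected = 2 * t_dist.sf(t_stat, df=n - 2)
        assert t_stat == pytest.approx(6.529, abs=1e-3)
        assert p_expected == pytest.approx(6.6e-5, rel=0.05)
        # engineer an eigengene with that exact correlation to a stage dummy
        samples = self.samples()
        ind = (samples["stage"] == "8cell").to_numpy(float)
        resid = np.tile([1.0, -1.0], 6)
        resid = resid - resid.dot(ind - ind.mean()) / np.sum(
            (ind - ind.mean()) ** 2
        ) * (ind - ind.mean())
        zi = (ind - ind.mean()) / np.std(ind - ind.mean())
        zr = (resid - resid.mean()) / np.std(resid - resid.mean())
        x = r * zi + np.sqrt(1 - r**2) * zr
        me = pd.DataFrame([x], index=["m"], columns=samples.index)
        res = module_trait_correlation(me, samples)
        row = res[(res.module == "m") & (res.stage == "8cell")].iloc[0]
        assert row.r == pytest.approx(0.9, abs=1e-10)
        assert row.p == pytest.approx(p_expected, rel=1e-6)

    def test_planted_rising_module_peaks_at_final_stage(self, planted):
        expr, samples, truth = planted
        tom = tom_similarity(adjacency(correlation_matrix(expr), 8))
        mods = detect_modules(tom)
        me = module_eigengenes(expr, mods)
        res = module_trait_correlation(me, samples)
        # find the detected module matching the planted rising trend (M1)
        rising = max(
            me.values.index,
            key=lambda m: abs(
                np.corrcoef(me.values.loc[m], truth.eigengenes.loc["M1"])[0, 1]
            ),
        )
        sub = res[res.module == rising].set_index("stage")["r"].abs()
        assert sub.idxmax() in ("32cell", "8cell")  # extreme stages of a trend

    def test_constant_stage_yields_nan(self):
        samples = pd.DataFrame(
            {"stage": ["x"] * 6}, index=[f"s{i}" for i in range(6)]
        )
        me = pd.DataFrame(
            [np.arange(6.0)], index=["m"], columns=samples.index
        )
        res = module_trait_correlation(me, samples)
        assert np.isnan(res.iloc[0].r)
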