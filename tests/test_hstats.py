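import numpy as np
import pytest
from scipy import stats

import myoscreen as ms
from myoscreen.hstats import NestedDataset


def make_nested(icc, n_preps, cells, seed, mean=3.67, total_sd=1.0):
    return ms.gen_nested_dataset(ms.NestedDesign(
        n_preps, cells, mean,
        np.sqrt(icc) * total_sd, np.sqrt(1 - icc) * total_sd, seed=seed,
    ))


class TestVarianceComponents:
    def test_mom_matches_hand_derived_anova(self):
        """Balanced 2x2 toys against closed-form one-way ANOVA values."""
        # {1,1},{3,3}: MSB=4, MSW=0, m'=2 -> sb2=2, sw2=0
        d = NestedDataset(values=np.array([1.0, 1, 3, 3]),
                          cluster_ids=np.array([0, 0, 1, 1]))
        sb2, sw2 = ms.variance_components_mom(d)
        assert sb2 == pytest.approx(2.0)
        assert sw2 == pytest.approx(0.0)
        # {1,2},{3,4}: MSB=4, MSW=0.5, m'=2 -> sb2=1.75, sw2=0.5
        d2 = NestedDataset(values=np.array([1.0, 2, 3, 4]),
                           cluster_ids=np.array([0, 0, 1, 1]))
        sb2, sw2 = ms.variance_components_mom(d2)
        assert sb2 == pytest.approx(1.75)
        assert sw2 == pytest.approx(0.5)

    def test_reml_agrees_with_statsmodels_mixedlm(self):
        """Dual-route check: profiled REML vs statsmodels MixedLM (REML)."""
        import pandas as pd
        import statsmodels.formula.api as smf

        data = make_nested(0.25, 6, 25, seed=4)
        fit = ms.fit_two_level(data)
        frame = pd.DataFrame({"y": data.values, "g": data.cluster_ids})
        sm_fit = smf.mixedlm("y ~ 1", frame, groups=frame["g"]).fit(reml=True)
        assert fit.sigma_w2 == pytest.approx(float(sm_fit.scale), rel=1e-3)
        assert fit.sigma_b2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2)
        assert fit.grand_mean == pytest.approx(float(sm_fit.params["Intercept"]), rel=1e-4)

    def test_reml_and_mom_agree_on_balanced_design(self):
        """Within 5% on balanced data with n >= 30 per cluster."""
        data = make_nested(0.3, 8, 40, seed=9)
        reml = ms.fit_two_level(data, estimator="reml")
        sb2, sw2 = ms.variance_components_mom(data)
        assert reml.sigma_w2 == pytest.approx(sw2, rel=0.05)
        assert reml.sigma_b2 == pytest.approx(sb2, rel=0.05)


class TestFitTwoLevel:
    def test_no_clustering_limit(self):
        """sigma_b = 0: icc ~ 0, grand mean ~ simple mean, se ~ simple SE."""
        iccs, se_ratios = [], []
        for seed in range(30):
            data = make_nested(0.0, 5, 45, seed=seed)
            fit = ms.fit_two_level(data)
            iccs.append(fit.icc)
            se_ratios.append(fit.se / fit.simple_se)
            assert fit.grand_mean == pytest.approx(fit.simple_mean, abs=0.1)
        assert np.median(iccs) < 0.02
        assert np.median(se_ratios) == pytest.approx(1.0, abs=0.1)

    def test_icc_recovery_at_printed_clustering(self):
        """Generator ICC 0.185, 5x45: estimates center on the truth."""
        iccs = [ms.fit_two_level(make_nested(0.185, 5, 45, seed=s)).icc
                for s in range(100)]
        assert np.median(iccs) == pytest.approx(0.185, abs=0.04)

    def test_identical_values_degenerate(self):
        d = NestedDataset(values=np.full(10, 2.5),
                          cluster_ids=np.repeat([0, 1], 5))
        fit = ms.fit_two_level(d)
        assert fit.degenerate
        assert fit.icc == 0.0 and fit.sigma_b2 == 0.0

    def test_requires_two_clusters(self):
        d = NestedDataset(values=np.arange(5.0), cluster_ids=np.zeros(5))
        with pytest.raises(ValueError, match="2 clusters"):
            ms.fit_two_level(d)

    def test_design_effect_law(self):
        """Balanced: hierarchical SE^2 ~ simple SE^2 * (1 + (m-1)*icc)."""
        m, icc = 45, 0.2
        ratios = []
        for seed in range(60):
            data = make_nested(icc, 6, m, seed=seed)
            fit = ms.fit_two_level(data)
            # use the known generator icc for the law, estimated se ratio
            ratios.append(fit.se**2 / fit.simple_se**2)
        expected = 1 + (m - 1) * icc
        assert np.mean(ratios) == pytest.approx(expected, rel=0.25)

    def test_estimator_consistency_many_preps(self):
        """Bias vanishes as the number of preparations grows (100 preps)."""
        iccs = [ms.fit_two_level(make_nested(0.2, 100, 20, seed=s)).icc
                for s in range(20)]
        assert np.mean(iccs) == pytest.approx(0.2, abs=0.02)

    def test_icc_bounds_and_se_inflation(self):
        for seed in range(10):
            fit = ms.fit_two_level(make_nested(0.3, 5, 30, seed=seed))
            assert 0.0 <= fit.icc < 1.0
            assert fit.eff_df <= fit.n_total - 1
            if fit.icc > 0:
                assert fit.se >= fit.simple_se * 0.99


class TestHierarchicalTTest:
    def test_identical_groups(self):
        data = make_nested(0.2, 5, 20, seed=1)
        res = ms.hierarchical_ttest(data, data)
        assert res.hierarchical_t == pytest.approx(0.0, abs=1e-10)
        assert res.hierarchical_p == pytest.approx(1.0)

    def test_single_cluster_group_falls_back(self):
        a = make_nested(0.2, 5, 20, seed=1)
        b = NestedDataset(values=np.random.default_rng(0).normal(size=20),
                          cluster_ids=np.zeros(20))
        with pytest.warns(UserWarning, match="fewer than 2 clusters"):
            res = ms.hierarchical_ttest(a, b)
        assert np.isnan(res.hierarchical_p)
        assert np.isfinite(res.simple_p)

    def test_pseudoreplication_pattern(self):
        """Clustered null data: conventional test rejects, hierarchical not.

        Mirrors the reported contrast where an unpaired t-test on pooled
        cells found a difference between dye-loaded and control cells that
        the cluster-corrected test did not support.
        """
        hits = []
        for seed in range(40):
            a = make_nested(0.25, 5, 45, seed=2 * seed)
            b = make_nested(0.25, 7, 45, seed=2 * seed + 1)
            res = ms.hierarchical_ttest(a, b)
            hits.append((res.simple_p < 0.05, res.hierarchical_p < 0.05))
        naive_rate = np.mean([h[0] for h in hits])
        hier_rate = np.mean([h[1] for h in hits])
        assert naive_rate > 0.25
        assert hier_rate < 0.15

    def test_suitability_flags(self):
        clustered = make_nested(0.4, 6, 40, seed=3)
        res = ms.hierarchical_ttest(clustered, make_nested(0.4, 6, 40, seed=4))
        assert res.suitability == "hierarchical"
        flat_a = make_nested(0.0, 6, 40, seed=5)
        flat_b = make_nested(0.0, 6, 40, seed=6)
        res2 = ms.hierarchical_ttest(flat_a, flat_b)
        assert res2.suitability == "conventional"


class TestConventionalTests:
    def test_identical_paired_samples(self):
        x = np.arange(10.0)
        stat, p, used = ms.conventional_tests(x, x, paired=True, force_t=True)
        assert stat == 0.0 and p == 1.0
        assert used == "paired_t"

    def test_matches_textbook_two_sample_t(self):
        """Agreement with the closed-form pooled-variance t statistic."""
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        stat, p, used = ms.conventional_tests(a, b, force_t=True)
        sp2 = ((49 * a.var(ddof=1)) + (49 * b.var(ddof=1))) / 98
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 50))
        p_manual = 2 * stats.t.sf(abs(t_manual), 98)
        assert stat == pytest.approx(t_manual)
        assert p == pytest.approx(p_manual)
        assert p < 0.05

    def test_heavy_tails_route_to_wilcoxon(self):
        rng = np.random.default_rng(3)
        a = rng.standard_cauchy(80)
        b = rng.standard_cauchy(80)
        _, _, used = ms.conventional_tests(a, b)
        assert used == "wilcoxon"

    def test_small_sample_raises(self):
        with pytest.raises(ValueError, match="n >= 3"):
            ms.conventional_tests([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPseudoreplicationCurve:
    def test_rates_behave_across_icc(self):
        """icc=0: both ~ alpha; icc=0.3 with small preps: naive inflated."""
        tab = ms.pseudoreplication_curve([0.0, 0.3], n_preps=3, cells_per_prep=50,
                                         n_reps=500, seed=21)
        row0 = tab[tab.icc == 0.0].iloc[0]
        row3 = tab[tab.icc == 0.3].iloc[0]
        assert row0.naive_type1 == pytest.approx(0.05, abs=0.03)
        assert row3.naive_type1 > 0.2
        assert row3.naive_type1 > row0.naive_type1

    def test_effective_df_collapse(self):
        """With 5-7 preps, eff df collapse far below the cell count.

        Hundreds of cells from a handful of hearts carry only a few
        independent degrees of freedom once clustering is acknowledged.
        """
        dfs = []
        for seed in range(20):
            fit = ms.fit_two_level(make_nested(0.185, 6, 80, seed=seed))
            dfs.append(fit.eff_df)
        assert np.median(dfs) < 30
        assert all(df < 480 for df in dfs)
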