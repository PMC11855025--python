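"""Cauchy combination, empirical Fisher, genotype correlation, region pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

import triadgxe as tg
from triadgxe.pooling import assign_regions, fisher_statistic, plot_table


class TestCauchy:
    def test_identical_inputs_return_the_common_p(self):
        for p in (0.05, 0.32, 0.9):
            assert tg.cauchy_combine([p] * 5) == pytest.approx(p, abs=1e-12)

    def test_single_p_is_identity(self):
        assert tg.cauchy_combine([0.32]) == pytest.approx(0.32, abs=1e-12)

    def test_two_value_example(self):
        # T = (tan(0.49 pi) + tan(0)) / 2; p = 0.5 - arctan(T)/pi
        assert tg.cauchy_combine([0.01, 0.5]) == pytest.approx(0.0199, abs=2e-4)

    def test_rejects_boundary_pvalues(self):
        for bad in ([0.0, 0.5], [0.5, 1.0], [-0.1], []):
            with pytest.raises(ValueError):
                tg.cauchy_combine(bad)

    def test_weights_validated(self):
        with pytest.raises(ValueError, match="weights"):
            tg.cauchy_combine([0.1, 0.2], weights=[-1.0, 2.0])

    @given(st.lists(st.floats(1e-6, 1 - 1e-6), min_size=2, max_size=6),
           st.integers(0, 5), st.floats(0.1, 0.9))
    @settings(deadline=None, max_examples=80)
    def test_monotone_in_each_argument(self, ps, idx, shrink):
        """Decreasing any single p-value never increases the combined p."""
        ps = list(ps)
        i = idx % len(ps)
        smaller = list(ps)
        smaller[i] = ps[i] * shrink
        assert tg.cauchy_combine(smaller) <= tg.cauchy_combine(ps) + 1e-12


class TestFisherEmpirical:
    def test_matches_analytic_tail_under_independence(self):
        p = np.array([0.5, 0.5])
        emp = tg.fisher_empirical(p, np.eye(2), B=100_000, seed=4)
        exact = chi2.sf(fisher_statistic(p), df=4)  # = e^{-F/2}(1+F/2) ~ 0.597
        mcse = np.sqrt(exact * (1 - exact) / 100_000)
        assert abs(emp - exact) < 3 * mcse
        assert exact == pytest.approx(0.5965, abs=1e-3)

    def test_duplicated_p_adds_no_information(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        emp = tg.fisher_empirical(np.array([0.3, 0.3]), R, B=50_000, seed=0)
        assert emp == pytest.approx(0.3, abs=0.02)

    def test_single_p_recovered(self):
        emp = tg.fisher_empirical(np.array([0.12]), np.eye(1), B=50_000, seed=1)
        assert emp == pytest.approx(0.12, abs=0.01)

    def test_deterministic_given_seed_and_warns_small_B(self):
        p = np.array([0.2, 0.4, 0.6])
        a = tg.fisher_empirical(p, np.eye(3), B=5_000, seed=9)
        b = tg.fisher_empirical(p, np.eye(3), B=5_000, seed=9)
        assert a == b
        with pytest.warns(UserWarning, match="resolution"):
            tg.fisher_empirical(p, np.eye(3), B=500, seed=0)

    def test_null_uniformity_under_ld(self, rng):
        """Empirical Fisher p-values are ~uniform under the global null when
        the null draws use the true p-value correlation structure."""
        k, r, n_reg = 4, 0.7, 300
        L = np.linalg.cholesky(np.full((k, k), r) + (1 - r) * np.eye(k))
        from scipy.stats import kstest, norm
        pooled = []
        for i in range(n_reg):
            z = L @ rng.standard_normal(k)
            p = 2 * norm.sf(np.abs(z))
            pooled.append(tg.fisher_empirical(p, L @ L.T, B=2_000, seed=int(i)))
        assert kstest(pooled, "uniform").pvalue > 0.01


class TestGenotypeCorrelation:
    def test_duplicated_snp_gives_unit_correlation(self):
        sc = tg.Scenario(n_triads=200, n_case_mother_dyads=0,
                         n_case_father_dyads=0, blocks=((2, 0.95),))
        co = tg.simulate_cohort(sc, seed=2)
        co.father_gt[:, 1] = co.father_gt[:, 0]
        co.mother_gt[:, 1] = co.mother_gt[:, 0]
        R = tg.genotype_correlation(co)
        assert R[0, 1] == pytest.approx(1.0, abs=1e-5)

    def test_independent_snps_have_small_correlation(self):
        sc = tg.Scenario(n_triads=1000, n_case_mother_dyads=0,
                         n_case_father_dyads=0, blocks=((1, 0.0), (1, 0.0)))
        co = tg.simulate_cohort(sc, seed=3)
        R = tg.genotype_correlation(co)
        assert abs(R[0, 1]) <= 3.5 / np.sqrt(2000)  # 2000 founders

    def test_matches_direct_pearson_formula(self):
        sc = tg.Scenario(n_triads=60, n_case_mother_dyads=0,
                         n_case_father_dyads=0, blocks=((2, 0.5),))
        co = tg.simulate_cohort(sc, seed=6)
        d = np.vstack([co.mother_gt, co.father_gt]).astype(float)
        x, y = d[:, 0], d[:, 1]
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        R = tg.genotype_correlation(co, eps=0.0)
        assert R[0, 1] == pytest.approx(expected, abs=1e-10)

    def test_monomorphic_snp_set_to_identity(self, caplog):
        sc = tg.Scenario(n_triads=50, n_case_mother_dyads=0,
                         n_case_father_dyads=0, blocks=((2, 0.0),))
        co = tg.simulate_cohort(sc, seed=1)
        co.mother_gt[:, 1] = 0
        co.father_gt[:, 1] = 0
        with caplog.at_level("WARNING"):
            R = tg.genotype_correlation(co)
        assert R[0, 1] == pytest.approx(0.0, abs=1e-9)
        assert R[1, 1] == pytest.approx(1.0)


class TestRegionPooling:
    def _scan_and_regions(self, pvals):
        sc = tg.Scenario(n_triads=30, n_case_mother_dyads=0, n_case_father_dyads=0,
                         blocks=((len(pvals), 0.2),))
        co = tg.simulate_cohort(sc, seed=5)
        scan = pd.DataFrame({"snp_id": co.snps["snp_id"], "wald_p": pvals})
        return scan, tg.scenario_regions(sc), co

    def test_pooled_is_min_of_both_methods(self):
        scan, regions, co = self._scan_and_regions([0.01, 0.2, 0.8])
        out = tg.pool_regions(scan, regions, co, B=5_000, seed=1, alpha=0.05)
        row = out.iloc[0]
        assert row["pooled_p"] == min(row["fisher_emp_p"], row["cauchy_p"])
        assert row["k"] == 3

    def test_bonferroni_threshold_for_twelve_regions(self):
        regions = pd.DataFrame({"chrom": ["1"] * 12,
                                "start": np.arange(12) * 10_000,
                                "end": np.arange(1, 13) * 10_000,
                                "region_name": [f"r{i}" for i in range(12)]})
        sc = tg.Scenario(n_triads=20, n_case_mother_dyads=0, n_case_father_dyads=0)
        co = tg.simulate_cohort(sc, seed=1)
        scan = pd.DataFrame({"snp_id": co.snps["snp_id"], "wald_p": [0.5]})
        out = tg.pool_regions(scan, regions, co, B=1_000, seed=0, alpha=0.05)
        assert out["bonferroni_alpha"].iloc[0] == pytest.approx(0.05 / 12, abs=1e-9)
        assert out["bonferroni_alpha"].iloc[0] == pytest.approx(0.0041667, abs=1e-6)

    def test_all_near_one_pvalues_not_significant(self):
        scan, regions, co = self._scan_and_regions([1.0 - 1e-12] * 4)
        out = tg.pool_regions(scan, regions, co, B=2_000, seed=3)
        assert out.iloc[0]["pooled_p"] > 0.9
        assert not out.iloc[0]["significant"]

    def test_failed_snps_dropped_with_count(self):
        scan, regions, co = self._scan_and_regions([0.2, np.nan, 0.4])
        out = tg.pool_regions(scan, regions, co, B=2_000, seed=0)
        assert out.iloc[0]["k"] == 2
        assert out.iloc[0]["n_failed_snps"] == 1

    def test_region_with_no_surviving_snps(self):
        scan, regions, co = self._scan_and_regions([np.nan, np.nan])
        out = tg.pool_regions(scan, regions, co, B=2_000, seed=0)
        assert np.isnan(out.iloc[0]["pooled_p"])
        assert not out.iloc[0]["significant"]

    def test_assign_regions_half_open(self):
        snps = pd.DataFrame({"snp_id": ["a", "b"], "chrom": ["1", "1"],
                             "pos": [100, 101]})
        regions = pd.DataFrame({"chrom": ["1"], "start": [99], "end": [100],
                                "region_name": ["r"]})
        got = assign_regions(snps, regions)
        assert got.tolist() == ["r", None]  # pos 100 -> 0-based 99 in [99,100)

    def test_plot_table_has_r2_to_top(self):
        scan, regions, co = self._scan_and_regions([0.01, 0.2, 0.8])
        scan[["chrom", "pos"]] = co.snps[["chrom", "pos"]]
        tab = plot_table(scan, co, "region1", regions)
        assert tab["r2_top"].iloc[0] == pytest.approx(1.0)
        assert np.all((0 <= tab["r2_top"]) & (tab["r2_top"] <= 1))
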