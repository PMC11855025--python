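"""Origin categories, conditional probabilities, fits and Wald tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

import triadgxe as tg
from triadgxe.families import MISSING
from triadgxe.likelihood import (
    CAT_AM, CAT_AF, CAT_M, CAT_F, PatternCounts, fit_patterns,
)


def count_transmissions(cohort, snp=0):
    """T (minor) and NT (major) transmissions from heterozygous parents,
    plus transmitted/untransmitted minor totals over all parents.

    Determined by (m, f, c) alone: hom-minor parents always transmit a minor
    allele, so het transmissions are c minus those; the double-het ambiguous
    triad contributes one T and one NT regardless of origin.
    """
    m = cohort.mother_gt[:, snp].astype(int)
    f = cohort.father_gt[:, snp].astype(int)
    c = cohort.child_gt[:, snp].astype(int)
    het = (m == 1).astype(int) + (f == 1).astype(int)
    t_het = c - (m == 2).astype(int) - (f == 2).astype(int)
    T, NT = int(t_het.sum()), int((het - t_het).sum())
    hom = int((m == 2).sum() + (f == 2).sum())
    return T, NT, T + hom, NT + hom, 2 * len(m)


class TestCategories:
    def test_sixteen_origin_resolved_fifteen_observable(self):
        cats = tg.enumerate_origin_categories()
        assert len(cats) == 16
        observable = cats[["m", "f", "c"]].drop_duplicates()
        assert len(observable) == 15
        ambiguous = cats[(cats.m == 1) & (cats.f == 1) & (cats.c == 1)]
        assert len(ambiguous) == 2  # only origin-ambiguous configuration

    def test_prior_half_frequency_double_het(self):
        prior = tg.origin_prior(0.5)
        k = int(np.flatnonzero((CAT_M == 1) & (CAT_F == 1)
                               & (CAT_AM == 1) & (CAT_AF == 0))[0])
        assert prior[k] == pytest.approx(0.5 * 0.5 * 0.5 * 0.5)

    @given(st.floats(0.01, 0.99))
    @settings(deadline=None, max_examples=50)
    def test_prior_normalizes(self, q):
        assert tg.origin_prior(q).sum() == pytest.approx(1.0, abs=1e-12)

    @given(st.floats(0.05, 0.95), st.floats(-1.5, 1.5), st.floats(-1.5, 1.5),
           st.floats(-1.5, 1.5))
    @settings(deadline=None, max_examples=50)
    def test_conditional_probabilities_normalize(self, q, lrm, lcm, lcf):
        params = tg.ParamVector(q=q, log_rm=lrm, log_rcm=lcm, log_rcf=lcf)
        spec = tg.ModelSpec(effects=("maternal_dose", "poo"))
        p = tg.category_probability(params, spec)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (p >= 0).all()

    def test_null_conditional_equals_prior(self):
        params = tg.ParamVector(q=0.3)
        np.testing.assert_allclose(
            tg.category_probability(params, tg.ModelSpec(effects=("poo",))),
            tg.origin_prior(0.3), atol=1e-12)

    def test_poo_transmission_odds(self):
        # Rcm=2, Rcf=1, q=0.5: a het mother transmits the minor allele wp 2/3
        params = tg.ParamVector(q=0.5, log_rcm=np.log(2.0), log_rcf=0.0)
        p = tg.category_probability(params, tg.ModelSpec(effects=("poo",)))
        het_m = CAT_M == 1
        frac = p[het_m & (CAT_AM == 1)].sum() / p[het_m].sum()
        assert frac == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_maternal_genotype_enrichment(self):
        # Rm=2, q=0.5: P(m=2)/P(m=0) among case mothers = 2^2 * q^2/(1-q)^2 = 4
        params = tg.ParamVector(q=0.5, log_rm=np.log(2.0))
        p = tg.category_probability(params, tg.ModelSpec(effects=("maternal_dose",)))
        assert p[CAT_M == 2].sum() / p[CAT_M == 0].sum() == pytest.approx(4.0)

    def test_invalid_q_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tg.origin_prior(1.5)


class TestFamilyLoglik:
    def test_complete_null_triad_is_log_prior(self):
        params = tg.ParamVector(q=0.5)
        spec = tg.ModelSpec(effects=("child_dose",))
        expected = np.log(0.25 * 0.25)  # pi(m=0) * pi(f=0), tau=1
        assert tg.family_loglik(0, 0, 0, params, spec) == pytest.approx(expected)

    def test_ambiguous_triad_sums_both_origins(self):
        params = tg.ParamVector(q=0.3, log_rcm=0.6, log_rcf=-0.2)
        spec = tg.ModelSpec(effects=("poo",))
        probs = tg.category_probability(params, spec)
        both = (CAT_M == 1) & (CAT_F == 1) & (CAT_AM + CAT_AF == 1)
        assert tg.family_loglik(1, 1, 1, params, spec) == pytest.approx(
            np.log(probs[both].sum()))

    @pytest.mark.parametrize("m,c", [(0, 0), (1, 1), (2, 2), (1, 0)])
    def test_dyad_marginalizes_missing_father(self, m, c):
        params = tg.ParamVector(q=0.27, log_rm=0.3, log_rcm=0.5, log_rcf=-0.4)
        spec = tg.ModelSpec(effects=("maternal_dose", "poo"))
        lls = [tg.family_loglik(m, f, c, params, spec) for f in (0, 1, 2)]
        assert tg.family_loglik(m, MISSING, c, params, spec) == pytest.approx(
            logsumexp(lls), abs=1e-12)

    def test_impossible_triad_is_minus_inf(self):
        assert tg.family_loglik(0, 0, 2, tg.ParamVector(q=0.4)) == -np.inf

    @given(st.integers(0, 15), st.floats(0.1, 0.9), st.floats(-1.0, 1.0),
           st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
    @settings(deadline=None, max_examples=60)
    def test_allele_relabeling_invariance(self, k, q, lrm, lcm, lcf):
        """Flipping minor/other (doses 2-g, q->1-q, negated log RRs) leaves
        the family log-likelihood unchanged; the model has no preferred
        allele labelling."""
        spec = tg.ModelSpec(effects=("maternal_dose", "poo"))
        m, f, c = int(CAT_M[k]), int(CAT_F[k]), int(CAT_AM[k] + CAT_AF[k])
        p1 = tg.ParamVector(q=q, log_rm=lrm, log_rcm=lcm, log_rcf=lcf)
        p2 = tg.ParamVector(q=1 - q, log_rm=-lrm, log_rcm=-lcm, log_rcf=-lcf)
        ll1 = tg.family_loglik(m, f, c, p1, spec)
        ll2 = tg.family_loglik(2 - m, 2 - f, 2 - c, p2, spec)
        assert ll1 == pytest.approx(ll2, abs=1e-9)


class TestFit:
    def test_tdt_closed_form_conditioned(self):
        sc = tg.Scenario(n_triads=500, n_case_mother_dyads=0,
                         n_case_father_dyads=0, rc=(1.8, 1.8))
        co = tg.simulate_cohort(sc, seed=3)
        T, NT, *_ = count_transmissions(co)
        fit = tg.fit_model(co, 0, tg.ModelSpec(effects=("child_dose",),
                                               conditional_on_parents=True))
        assert fit.converged
        assert np.exp(fit.estimate("log_rc")) == pytest.approx(
            tg.tdt_transmission_ratio(T, NT), rel=1e-6)

    def test_allele_odds_ratio_closed_form_full_likelihood(self):
        sc = tg.Scenario(n_triads=500, n_case_mother_dyads=0,
                         n_case_father_dyads=0, rc=(1.8, 1.8))
        co = tg.simulate_cohort(sc, seed=3)
        *_, tr, un, n_par = count_transmissions(co)
        fit = tg.fit_model(co, 0, tg.ModelSpec(effects=("child_dose",)))
        assert fit.converged
        assert np.exp(fit.estimate("log_rc")) == pytest.approx(
            tg.allele_odds_ratio(tr, un, n_par), rel=1e-6)

    def test_dyads_contribute_information(self):
        sc = tg.Scenario(n_triads=300, n_case_mother_dyads=80,
                         n_case_father_dyads=80, rc=(1.5, 1.5))
        co = tg.simulate_cohort(sc, seed=9)
        spec = tg.ModelSpec(effects=("child_dose",))
        fit_all = tg.fit_model(co, 0, spec)
        fit_triads = tg.fit_model(co, 0, spec,
                                  co.family_kind == tg.FamilyKind.TRIAD)
        assert fit_all.n_families_used == 460
        assert fit_all.se("log_rc") < fit_triads.se("log_rc")

    def test_null_recovery_and_coverage(self, null_triads):
        spec = tg.ModelSpec(effects=("maternal_dose", "poo"))
        fit = tg.fit_model(null_triads, 0, spec)
        assert fit.converged
        for name in ("log_rm", "log_rcm", "log_rcf"):
            assert abs(fit.estimate(name)) < 3.5 * fit.se(name)
        assert abs(fit.params.q - 0.25) < 0.02

    def test_maternal_recovery(self):
        sc = tg.Scenario(n_triads=5000, n_case_mother_dyads=0,
                         n_case_father_dyads=0, rm=(1.5, 1.5))
        co = tg.simulate_cohort(sc, seed=21)
        fit = tg.fit_model(co, 0, tg.ModelSpec(effects=("child_dose", "maternal_dose")))
        est, se = fit.effect_estimate("maternal_dose")
        assert abs(est - np.log(1.5)) < 3 * se

    def test_degenerate_monomorphic_flagged_not_raised(self):
        pats = PatternCounts(np.zeros(50, int), np.zeros(50, int), np.zeros(50, int))
        fit = fit_patterns(pats, tg.ModelSpec(effects=("child_dose",)))
        assert not fit.converged
        assert np.isinf(fit.se("log_rc"))

    def test_empty_family_set(self):
        pats = PatternCounts(np.array([]), np.array([]), np.array([]))
        fit = fit_patterns(pats, tg.ModelSpec(effects=("child_dose",)))
        assert fit.n_families_used == 0 and not fit.converged


class TestWald:
    def test_null_estimate_gives_p_one(self, null_triads):
        fit = tg.fit_model(null_triads, 0, tg.ModelSpec(effects=("child_dose",)))
        fit.x[fit.param_names.index("log_rc")] = 0.0  # exact null estimate
        res = tg.wald_main_effect(fit, "child")
        assert res.p_value == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_se_reconstruction_from_printed_ci(self):
        # RR 1.48 [1.07, 2.08] => SE(log RR) ~ (log 2.08 - log 1.07)/3.92
        se = (np.log(2.08) - np.log(1.07)) / (2 * 1.959963985)
        assert se == pytest.approx(0.170, abs=0.002)

    def test_interaction_from_published_cis(self):
        z, p = tg.wald_from_cis(1.48, (1.07, 2.08), 0.73, (0.52, 1.02))
        assert abs(z) == pytest.approx(2.9, abs=0.1)
        assert p == pytest.approx(0.0029, abs=0.002)

    def test_identical_strata_give_p_one(self, null_triads):
        spec = tg.ModelSpec(effects=("child_dose", "maternal_dose"))
        fit = tg.fit_model(null_triads, 0, spec)
        res = tg.wald_gxe(fit, fit, "maternal")
        assert res.wald_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_nonconverged_stratum_yields_missing_p(self, null_triads):
        spec = tg.ModelSpec(effects=("child_dose",))
        good = tg.fit_model(null_triads, 0, spec)
        bad = fit_patterns(PatternCounts(np.array([]), np.array([]), np.array([])),
                           spec)
        res = tg.wald_gxe(good, bad, "child")
        assert not res.converged and np.isnan(res.p_value)


class TestScan:
    def test_scan_shape_and_empty(self, null_triads):
        scan = tg.gxe_scan(null_triads, "maternal", "smoking")
        assert len(scan) == null_triads.n_snps
        assert {"snp_id", "wald_p", "stratum0_rr", "stratum1_rr"} <= set(scan.columns)
        empty = tg.gxe_scan(null_triads, "maternal", "smoking", snps=[])
        assert len(empty) == 0

    def test_injected_signal_attains_minimum_p(self):
        sc = tg.Scenario(n_triads=2000, n_case_mother_dyads=0,
                         n_case_father_dyads=0, blocks=((5, 0.3),),
                         causal_snp=2, rm=(0.6, 2.5), exposure_prevalence=0.5,
                         missing_exposure_rate=0.0)
        co = tg.simulate_cohort(sc, seed=17)
        scan = tg.gxe_scan(co, "maternal", "smoking")
        assert scan["wald_p"].idxmin() == 2
        assert scan["wald_p"].min() < 1e-4

    def test_main_scan_detects_main_effect(self):
        sc = tg.Scenario(n_triads=3000, n_case_mother_dyads=0,
                         n_case_father_dyads=0, rm=(1.6, 1.6))
        co = tg.simulate_cohort(sc, seed=8)
        res = tg.main_scan(co, "maternal")
        assert res.loc[0, "p_value"] < 1e-3
        assert res.loc[0, "ci_low"] < 1.6 < res.loc[0, "ci_high"] * 2
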