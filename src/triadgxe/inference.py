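"""Wald tests for main genetic effects and gene-environment interaction.

The interaction test compares a log-scale effect (log relative risk for the
maternal/child models, log relative-risk ratio for the parent-of-origin
model) between two disjoint exposure strata fitted independently:

    W = (θ̂₁ − θ̂₀)² / (se₀² + se₁²),   p = P(χ²₁ ≥ W).

Families with a missing value of the tested exposure are excluded from that
scan only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .families import MISSING, Cohort
from .likelihood import FitResult, ModelSpec, fit_model

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))

#: scan-level effect name -> (ModelSpec effects, tested effect)
EFFECT_MODELS = {
    "maternal": (("child_dose", "maternal_dose"), "maternal_dose"),
    "maternal_only": (("maternal_dose",), "maternal_dose"),
    "poo": (("poo",), "poo"),
    "child": (("child_dose",), "child_dose"),
}


def model_spec_for(effect: str, **kw) -> ModelSpec:
    """ModelSpec for a named scan effect.

    'maternal' co-estimates the child dose effect with the maternal effect
    (the correlated-dose-safe default); 'maternal_only' drops the child term.
    """
    if effect not in EFFECT_MODELS:
        raise ValueError(f"unknown effect {effect!r}; expected one of {sorted(EFFECT_MODELS)}")
    return ModelSpec(effects=EFFECT_MODELS[effect][0], **kw)


def tested_parameter(effect: str) -> str:
    return EFFECT_MODELS[effect][1]


@dataclass
class MainEffectResult:
    effect: str
    log_rr: float
    se: float
    rr: float
    ci_low: float
    ci_high: float
    z: float
    p_value: float
    converged: bool


def wald_main_effect(fit: FitResult, effect: str) -> MainEffectResult:
    """Two-sided Wald test of a single log effect against 0 (RR = 1)."""
    tested = tested_parameter(effect) if effect in EFFECT_MODELS else effect
    est, se = fit.effect_estimate(tested)
    if not fit.converged or not np.isfinite(se) or se <= 0:
        return MainEffectResult(tested, est, np.inf, float(np.exp(est)),
                                np.nan, np.nan, np.nan, np.nan, False)
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return MainEffectResult(
        tested, est, se, float(np.exp(est)),
        float(np.exp(est - Z95 * se)), float(np.exp(est + Z95 * se)),
        float(z), float(p), True,
    )


@dataclass
class GxETestResult:
    """Wald interaction test between two exposure strata for one SNP."""

    snp_id: str
    effect: str
    theta_hat: float
    se_theta: float
    wald_stat: float
    p_value: float
    rr0: float
    ci0: tuple
    rr1: float
    ci1: tuple
    n0: int
    n1: int
    converged: bool


def wald_gxe(fit_unexposed: FitResult, fit_exposed: FitResult,
             effect: str, snp_id: str = "") -> GxETestResult:
    """Wald test of equality of a stratum effect; strata are disjoint."""
    tested = tested_parameter(effect) if effect in EFFECT_MODELS else effect
    e0, s0 = fit_unexposed.effect_estimate(tested)
    e1, s1 = fit_exposed.effect_estimate(tested)
    ok = (fit_unexposed.converged and fit_exposed.converged
          and np.isfinite(s0) and np.isfinite(s1))
    rr0, rr1 = float(np.exp(e0)), float(np.exp(e1))
    ci0 = (float(np.exp(e0 - Z95 * s0)), float(np.exp(e0 + Z95 * s0))) if ok else (np.nan, np.nan)
    ci1 = (float(np.exp(e1 - Z95 * s1)), float(np.exp(e1 + Z95 * s1))) if ok else (np.nan, np.nan)
    if not ok:
        return GxETestResult(snp_id, effect, np.nan, np.nan, np.nan, np.nan,
                             rr0, ci0, rr1, ci1,
                             fit_unexposed.n_families_used, fit_exposed.n_families_used, False)
    theta = e1 - e0
    se = float(np.sqrt(s0 ** 2 + s1 ** 2))
    w = (theta / se) ** 2
    p = float(stats.chi2.sf(w, df=1))
    return GxETestResult(snp_id, effect, float(theta), se, float(w), p,
                         rr0, ci0, rr1, ci1,
                         fit_unexposed.n_families_used, fit_exposed.n_families_used, True)


def wald_from_cis(rr0: float, ci0: tuple, rr1: float, ci1: tuple,
                  level: float = 0.95):
    """Reconstruct the interaction Wald z and p from printed RRs and CIs.

    The SE of each log effect is recovered as (log hi − log lo) / (2 z*);
    a consistency check against published stratified tables.
    """
    zs = float(stats.norm.ppf(0.5 + level / 2))
    s0 = (np.log(ci0[1]) - np.log(ci0[0])) / (2 * zs)
    s1 = (np.log(ci1[1]) - np.log(ci1[0])) / (2 * zs)
    theta = np.log(rr1) - np.log(rr0)
    z = theta / np.sqrt(s0 ** 2 + s1 ** 2)
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

_SCAN_COLUMNS = ["snp_id", "chrom", "pos", "minor", "other", "maf", "effect",
                 "n0", "n1", "stratum0_rr", "stratum0_lo", "stratum0_hi",
                 "stratum1_rr", "stratum1_lo", "stratum1_hi",
                 "theta", "se_theta", "wald_stat", "wald_p", "converged"]


def gxe_scan(cohort: Cohort, effect: str, exposure: str,
             snps=None, maternal_only: bool = False) -> pd.DataFrame:
    """Per-SNP gene-environment interaction Wald tests.

    Fits the model separately in the unexposed (0) and exposed (1) strata of
    ``exposure`` ('smoking' or 'folate') and tests the log effect difference.
    Per-SNP failures are recorded (``converged`` False, ``wald_p`` NaN) and
    the scan continues.
    """
    if effect == "maternal" and maternal_only:
        effect = "maternal_only"
    spec = model_spec_for(effect)
    expo = cohort.exposure(exposure)
    mask0, mask1 = expo == 0, expo == 1
    n_excl = int((expo == MISSING).sum())
    if n_excl:
        logger.info("%d famil(ies) with missing %s excluded from this scan",
                    n_excl, exposure)
    snp_list = list(range(cohort.n_snps)) if snps is None else list(snps)
    rows = []
    for snp in snp_list:
        j = snp if isinstance(snp, (int, np.integer)) else \
            int(cohort.snps.index[cohort.snps["snp_id"] == snp][0])
        meta = cohort.snps.iloc[j]
        try:
            fit0 = fit_model(cohort, j, spec, mask0)
            fit1 = fit_model(cohort, j, spec, mask1)
            res = wald_gxe(fit0, fit1, effect, snp_id=str(meta["snp_id"]))
        except Exception as exc:  # keep scanning
            logger.warning("SNP %s failed: %s", meta["snp_id"], exc)
            res = GxETestResult(str(meta["snp_id"]), effect, np.nan, np.nan,
                                np.nan, np.nan, np.nan, (np.nan, np.nan),
                                np.nan, (np.nan, np.nan), 0, 0, False)
        rows.append([res.snp_id, meta["chrom"], meta["pos"], meta["minor"],
                     meta["other"], meta["maf"], effect, res.n0, res.n1,
                     res.rr0, res.ci0[0], res.ci0[1],
                     res.rr1, res.ci1[0], res.ci1[1],
                     res.theta_hat, res.se_theta, res.wald_stat, res.p_value,
                     res.converged])
    return pd.DataFrame(rows, columns=_SCAN_COLUMNS)


def main_scan(cohort: Cohort, effect: str, snps=None,
              maternal_only: bool = False) -> pd.DataFrame:
    """Per-SNP main-effect Wald tests ignoring the environmental factors."""
    if effect == "maternal" and maternal_only:
        effect = "maternal_only"
    spec = model_spec_for(effect)
    snp_list = list(range(cohort.n_snps)) if snps is None else list(snps)
    rows = []
    for snp in snp_list:
        j = snp if isinstance(snp, (int, np.integer)) else \
            int(cohort.snps.index[cohort.snps["snp_id"] == snp][0])
        meta = cohort.snps.iloc[j]
        try:
            fit = fit_model(cohort, j, spec)
            res = wald_main_effect(fit, effect)
            rows.append([meta["snp_id"], meta["chrom"], meta["pos"], meta["minor"],
                         meta["other"], meta["maf"], effect, fit.n_families_used,
                         res.rr, res.ci_low, res.ci_high, res.z, res.p_value,
                         res.converged])
        except Exception as exc:
            logger.warning("SNP %s failed: %s", meta["snp_id"], exc)
            rows.append([meta["snp_id"], meta["chrom"], meta["pos"], meta["minor"],
                         meta["other"], meta["maf"], effect, 0,
                         np.nan, np.nan, np.nan, np.nan, np.nan, False])
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "minor", "other",
                                       "maf", "effect", "n", "rr", "ci_low",
                                       "ci_high", "z", "p_value", "converged"])
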