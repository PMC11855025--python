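"""Simulation-based power and type-I error for the interaction Wald tests.

Each replicate simulates a cohort under a :class:`~triadgxe.simulate.Scenario`,
fits the two exposure-stratum models at the causal SNP, performs the
gene-environment Wald test and counts a rejection when p < alpha.  Replicate
random streams derive from the master seed by a counter scheme
(``SeedSequence(seed, spawn_key=(i,))``), so results are independent of any
parallel scheduling and fully reproducible from the seed ledger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .inference import model_spec_for, wald_gxe
from .likelihood import fit_model
from .simulate import Scenario, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PowerResult:
    """Monte-Carlo power estimate with a Wilson 95% interval."""

    effect: str
    alpha: float
    n_replicates: int
    n_rejections: int
    n_nonconverged: int
    power: float
    ci_low: float
    ci_high: float
    master_seed: int
    replicate_keys: list = field(default_factory=list)

    def to_row(self) -> dict:
        return {
            "effect": self.effect, "alpha": self.alpha,
            "reps": self.n_replicates, "rejections": self.n_rejections,
            "nonconverged": self.n_nonconverged, "power": self.power,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def _replicate_rng(master_seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(i,)))


def estimate_power(scenario: Scenario, effect: str, alpha: float = 0.05,
                   reps: int = 500, seed: int = 0,
                   maternal_only: bool = False) -> PowerResult:
    """Rejection rate of the gene-environment Wald test under ``scenario``.

    Non-converged replicate fits are counted and reported separately; they
    are never counted as rejections, so the power estimate is conservative
    when convergence failures occur.
    """
    if reps < 100:
        logger.warning("reps=%d is small for a power estimate", reps)
    eff = "maternal_only" if (effect == "maternal" and maternal_only) else effect
    spec = model_spec_for(eff)
    n_rej = n_bad = 0
    keys = []
    for i in range(reps):
        rng = _replicate_rng(seed, i)
        keys.append(i)
        cohort = simulate_cohort(scenario, rng)
        expo = cohort.exposure(scenario.exposure)
        fit0 = fit_model(cohort, scenario.causal_snp, spec, expo == 0)
        fit1 = fit_model(cohort, scenario.causal_snp, spec, expo == 1)
        res = wald_gxe(fit0, fit1, eff)
        if not res.converged or not np.isfinite(res.p_value):
            n_bad += 1
            continue
        if res.p_value < alpha:
            n_rej += 1
    power = n_rej / reps
    lo, hi = proportion_confint(n_rej, reps, alpha=0.05, method="wilson")
    return PowerResult(effect, alpha, reps, n_rej, n_bad, power,
                       float(lo), float(hi), seed, keys)


def power_curve(scenario: Scenario, effect: str, effect_grid,
                alpha: float = 0.05, reps: int = 500, seed: int = 0) -> pd.DataFrame:
    """Power across a grid of exposed-stratum effect sizes.

    Each grid value g sets the exposed-stratum relative risk (maternal
    effect) or relative-risk ratio (parent-of-origin effect, split
    symmetrically as Rcm = √g, Rcf = 1/√g) with the unexposed stratum at the
    null, so g is the between-stratum effect ratio being detected.
    """
    rows = []
    for g_idx, g in enumerate(effect_grid):
        sc = scenario_with_effect(scenario, effect, float(g))
        res = estimate_power(sc, effect, alpha=alpha, reps=reps,
                             seed=int(np.random.SeedSequence(seed, spawn_key=(g_idx,))
                                      .generate_state(1)[0] % (2 ** 31)))
        row = res.to_row()
        row["effect_size"] = float(g)
        rows.append(row)
    cols = ["effect_size", "effect", "alpha", "reps", "rejections",
            "nonconverged", "power", "ci_low", "ci_high"]
    return pd.DataFrame(rows, columns=cols)


def scenario_with_effect(scenario: Scenario, effect: str, g: float) -> Scenario:
    """Scenario with exposed-stratum effect size g and null unexposed stratum."""
    from dataclasses import replace
    if effect in ("maternal", "maternal_only"):
        return replace(scenario, rm=(1.0, g), rcm=(1.0, 1.0), rcf=(1.0, 1.0))
    if effect == "poo":
        s = float(np.sqrt(g))
        return replace(scenario, rm=(1.0, 1.0), rcm=(1.0, s), rcf=(1.0, 1.0 / s))
    if effect == "child":
        return replace(scenario, rc=(1.0, g))
    raise ValueError(f"unknown effect {effect!r}")
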