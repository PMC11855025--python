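"""Synthetic case-parent triad/dyad cohorts with the design's exact structure.

Families are sampled *directly from the conditional-on-affected multinomial*
over origin-resolved genotype categories (see :mod:`triadgxe.likelihood`):
because every analysis in the package conditions on the child being affected,
no baseline risk or rejection step is needed — the baseline cancels.  This
makes the generator exact for the analysis model and fast.

Exposure is drawn independently of the parental mating type (the design's
identifying assumption); the exposed and unexposed strata have their own
relative-risk parameters.  Dyads are complete triads with the designated
parent's genotypes deleted.  Linkage disequilibrium within a block of SNPs is
produced by a latent Gaussian copula on haplotypes, calibrated so the founder
*dose* correlation matches the target; whole haplotypes are transmitted
(no recombination within a block), which propagates LD to the children.

Defaults mirror the study composition: 404 triads + 26 case-mother +
14 case-father dyads, periconceptional smoking prevalence 22.3% and
folic-acid supplementation 49.1%, CL/P : CPO ≈ 317 : 125 with 2/444 missing
subtype, and 17/444 missing smoking status.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import multivariate_normal
from scipy.optimize import brentq

from .families import MISSING, Cohort, FamilyKind, SUBTYPE_CLP, SUBTYPE_CPO, \
    SEX_MALE, SEX_FEMALE, make_snp_table
from .io import write_cohort  # re-exported: the generator's output surface
from .likelihood import CAT_M, CAT_F, CAT_AM, CAT_AF, ModelSpec, ParamVector, \
    category_probability

__all__ = [
    "Scenario", "simulate_cohort", "simulate_origin_categories",
    "simulate_ld_block", "scenario_regions", "paper_like_scenario",
    "study_margins_cohort", "write_cohort", "GENERATOR_SPEC",
]

logger = logging.getLogger(__name__)

#: the generator's penetrance model: maternal dose + origin-specific child terms
GENERATOR_SPEC = ModelSpec(effects=("maternal_dose", "poo"))


@dataclass
class Scenario:
    """Study conditions for one simulated cohort.

    Relative-risk pairs are (unexposed, exposed) for the exposure named in
    ``exposure``; ``rc`` is a per-allele child effect folded equally into
    both transmission origins.  ``blocks`` lists ``(n_snps, r)`` pairs of
    exchangeable-LD blocks (independent across blocks); ``causal_snp`` is the
    global index of the SNP carrying the risk parameters.
    """

    n_triads: int = 404
    n_case_mother_dyads: int = 26
    n_case_father_dyads: int = 14
    q: float = 0.25
    exposure: str = "smoking"
    exposure_prevalence: float | None = None
    rm: tuple = (1.0, 1.0)
    rc: tuple = (1.0, 1.0)
    rcm: tuple = (1.0, 1.0)
    rcf: tuple = (1.0, 1.0)
    blocks: tuple = ((1, 0.0),)
    causal_snp: int = 0
    smoking_prevalence: float = 99 / 444
    folate_prevalence: float = 218 / 444
    missing_exposure_rate: float = 17 / 444
    clp_fraction: float = 317 / 442
    missing_subtype_rate: float = 2 / 444
    male_fraction: float = 272 / 444
    clp_only_effects: bool = False

    def __post_init__(self):
        if not 0.0 < self.q <= 0.5:
            raise ValueError(f"q={self.q} must lie in (0, 0.5]")
        for name in ("rm", "rc", "rcm", "rcf"):
            pair = tuple(float(v) for v in np.atleast_1d(getattr(self, name)))
            if len(pair) == 1:
                pair = pair * 2
            if any(v <= 0 for v in pair):
                raise ValueError(f"{name} relative risks must be positive")
            setattr(self, name, pair)
        if min(self.n_triads, self.n_case_mother_dyads, self.n_case_father_dyads) < 0:
            raise ValueError("family counts must be nonnegative")
        self.blocks = tuple((int(k), float(r)) for k, r in self.blocks)
        for k, r in self.blocks:
            if not 0.0 <= r < 1.0:
                raise ValueError(f"block correlation r={r} must lie in [0, 1)")
        rho = self.active_prevalence
        if not 0.0 <= rho <= 1.0:
            raise ValueError("exposure prevalence must lie in [0, 1]")

    @property
    def n_families(self) -> int:
        return self.n_triads + self.n_case_mother_dyads + self.n_case_father_dyads

    @property
    def n_snps(self) -> int:
        return sum(k for k, _ in self.blocks)

    @property
    def active_prevalence(self) -> float:
        if self.exposure_prevalence is not None:
            return self.exposure_prevalence
        return {"smoking": self.smoking_prevalence,
                "folate": self.folate_prevalence}[self.exposure]

    def stratum_params(self, exposed: int) -> ParamVector:
        s = int(exposed)
        return ParamVector(
            q=self.q,
            log_rm=float(np.log(self.rm[s])),
            log_rcm=float(np.log(self.rcm[s] * self.rc[s])),
            log_rcf=float(np.log(self.rcf[s] * self.rc[s])),
        )

    @property
    def is_null(self) -> bool:
        return all(v == (1.0, 1.0) for v in (self.rm, self.rc, self.rcm, self.rcf))


def paper_like_scenario(**overrides) -> Scenario:
    """The desk-scale preset used for calibration and power tables.

    Study family composition (404 + 26 + 14), minor-allele frequency 0.25 and
    a balanced exposure (prevalence 0.5).
    """
    base = dict(q=0.25, exposure_prevalence=0.5)
    base.update(overrides)
    return Scenario(**base)


def study_margins_cohort() -> Cohort:
    """Deterministic 444-family cohort reproducing the study's margins.

    Family composition 404 triads + 26 case-mother + 14 case-father dyads;
    subtype split 317 CL/P, 125 CPO, 2 missing; 99 smoking-exposed (17
    missing), 218 folate-exposed, sex 272 male / 172 female, all allocated to
    match the published per-subtype counts.  Genotypes are a placeholder
    single SNP (all doses 0); use :func:`simulate_cohort` when genotypes
    matter.  Intended for exercising the cohort summary operations.
    """
    n = 444
    subtype = np.full(n, MISSING, dtype=np.int8)
    subtype[:317] = SUBTYPE_CLP
    subtype[317:442] = SUBTYPE_CPO
    sex = np.empty(n, dtype=np.int8)
    sex[:213] = SEX_MALE          # CL/P: 213 male, 104 female
    sex[213:317] = SEX_FEMALE
    sex[317:374] = SEX_MALE       # CPO: 57 male, 68 female
    sex[374:442] = SEX_FEMALE
    sex[442:] = SEX_MALE          # the 2 missing-subtype children
    smoking = np.zeros(n, dtype=np.int8)
    smoking[:73] = 1              # CL/P smokers
    smoking[317:343] = 1          # CPO smokers (26)
    smoking[300:317] = MISSING    # 17 missing smoking status
    folate = np.zeros(n, dtype=np.int8)
    folate[73:225] = 1            # 152 CL/P folate users
    folate[343:409] = 1           # 66 CPO folate users
    kinds = np.full(n, FamilyKind.TRIAD, dtype=np.int8)
    kinds[404:430] = FamilyKind.CASE_MOTHER_DYAD
    kinds[430:] = FamilyKind.CASE_FATHER_DYAD
    zeros = np.zeros((n, 1), dtype=np.int8)
    mother, father = zeros.copy(), zeros.copy()
    father[kinds == FamilyKind.CASE_MOTHER_DYAD] = MISSING
    mother[kinds == FamilyKind.CASE_FATHER_DYAD] = MISSING
    return Cohort(
        family_id=np.array([f"F{i + 1:05d}" for i in range(n)], dtype=object),
        family_kind=kinds,
        mother_gt=mother, father_gt=father, child_gt=zeros,
        smoking=smoking, folate=folate, subtype=subtype, child_sex=sex,
        snps=make_snp_table(["snp0001"], ["1"], [10_000], "A", "G", maf=0.0),
    )


# ---------------------------------------------------------------------------
# conditional category sampling
# ---------------------------------------------------------------------------

def simulate_origin_categories(n: int, params: ParamVector,
                               rng: np.random.Generator | int,
                               spec: ModelSpec = GENERATOR_SPEC) -> np.ndarray:
    """Draw origin-resolved category indices from P(cat | affected)."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    probs = category_probability(params, spec)
    return rng.choice(len(probs), size=n, p=probs)


# ---------------------------------------------------------------------------
# LD copula
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=256)
def _latent_corr(r: float, q: float) -> float:
    """Latent Gaussian correlation whose thresholded indicators have phi = r."""
    if r == 0.0:
        return 0.0
    t = ndtri(q)

    def phi(a: float) -> float:
        p11 = multivariate_normal(mean=[0, 0], cov=[[1, a], [a, 1]]).cdf([t, t])
        return (p11 - q * q) / (q * (1 - q)) - r

    return brentq(phi, 1e-9, 1 - 1e-9, xtol=1e-10)


def _haplotypes_unconditional(rng, n_hap: int, n_snps: int, a: float,
                              t: float) -> np.ndarray:
    g = rng.standard_normal(n_hap)
    z = np.sqrt(a) * g[:, None] + np.sqrt(1 - a) * rng.standard_normal((n_hap, n_snps))
    return (z < t).astype(np.int8)


def _haplotypes_given_causal(rng, causal_allele: np.ndarray, n_snps: int,
                             cpos: int, a: float, t: float) -> np.ndarray:
    """Block haplotypes conditional on the causal SNP's allele per haplotype."""
    n_hap = len(causal_allele)
    u = rng.random(n_hap)
    pt = ndtr(t)
    z_c = ndtri(np.where(causal_allele == 1, u * pt, pt + u * (1 - pt)))
    out = np.empty((n_hap, n_snps), dtype=np.int8)
    out[:, cpos] = causal_allele
    if n_snps > 1:
        g = np.sqrt(a) * z_c + np.sqrt(1 - a) * rng.standard_normal(n_hap)
        other = [j for j in range(n_snps) if j != cpos]
        z = np.sqrt(a) * g[:, None] + np.sqrt(1 - a) * rng.standard_normal(
            (n_hap, len(other)))
        out[:, other] = (z < t).astype(np.int8)
    return out


def simulate_ld_block(n_founders: int, n_snps: int, r: float, q: float,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Founder dose matrix for one exchangeable-LD block.

    Two copula haplotypes per founder; returned dose correlation approximates
    ``r`` (within ~±0.05 at n=2000).
    """
    if not 0.0 <= r < 1.0:
        raise ValueError(f"|r|={abs(r)} must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = _latent_corr(r, q)
    t = ndtri(q)
    haps = _haplotypes_unconditional(rng, 2 * n_founders, n_snps, a, t)
    return haps[::2] + haps[1::2]


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _snp_table(scenario: Scenario) -> pd.DataFrame:
    ids, chroms, poss = [], [], []
    j = 0
    for b, (k, _) in enumerate(scenario.blocks):
        base = 10_000 + 1_000_000 * b
        for local in range(k):
            ids.append(f"snp{j + 1:04d}")
            chroms.append("1")
            poss.append(base + 1_000 * local)
            j += 1
    return make_snp_table(ids, chroms, poss, "A", "G", maf=scenario.q)


def scenario_regions(scenario: Scenario) -> pd.DataFrame:
    """One BED-like region per LD block (0-based half-open)."""
    rows = []
    for b, (k, _) in enumerate(scenario.blocks):
        base = 10_000 + 1_000_000 * b
        rows.append(("1", base - 1, base + 1_000 * (k - 1), f"region{b + 1}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "region_name"])


def simulate_cohort(scenario: Scenario, seed: int | np.random.Generator = 0) -> Cohort:
    """Simulate one cohort under a :class:`Scenario`; deterministic given seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = scenario.n_families
    rho = scenario.active_prevalence

    exposed = rng.binomial(1, rho, size=n).astype(np.int8)
    subtype = np.where(rng.random(n) < scenario.clp_fraction, SUBTYPE_CLP, SUBTYPE_CPO
                       ).astype(np.int8)
    subtype[rng.random(n) < scenario.missing_subtype_rate] = MISSING

    # conditional category of the causal SNP per family (single uniform stream)
    cum = []
    for s in (0, 1):
        params = scenario.stratum_params(s)
        if scenario.clp_only_effects:
            null = ParamVector(q=scenario.q)
            cum.append((np.cumsum(category_probability(params, GENERATOR_SPEC)),
                        np.cumsum(category_probability(null, GENERATOR_SPEC))))
        else:
            c = np.cumsum(category_probability(params, GENERATOR_SPEC))
            cum.append((c, c))
    u = rng.random(n)
    cat = np.empty(n, dtype=int)
    for s in (0, 1):
        for is_cpo in (0, 1):
            sel = (exposed == s) & ((subtype != SUBTYPE_CLP) == bool(is_cpo))
            cum_s = cum[s][is_cpo]
            cat[sel] = np.searchsorted(cum_s, u[sel], side="right")

    m_c, f_c = CAT_M[cat], CAT_F[cat]
    tm, tf = CAT_AM[cat], CAT_AF[cat]          # transmitted causal alleles
    um, uf = m_c - tm, f_c - tf                # untransmitted causal alleles

    # per-family haplotypes across all SNPs: mT, mU, fT, fU
    k_total = scenario.n_snps
    if not 0 <= scenario.causal_snp < k_total:
        raise ValueError(f"causal_snp={scenario.causal_snp} outside the SNP range")
    haps = {name: np.empty((n, k_total), dtype=np.int8)
            for name in ("mT", "mU", "fT", "fU")}
    causal_alleles = {"mT": tm, "mU": um, "fT": tf, "fU": uf}
    t_thr = ndtri(scenario.q)
    offset = 0
    for b, (k, r) in enumerate(scenario.blocks):
        a = _latent_corr(r, scenario.q)
        cols = slice(offset, offset + k)
        has_causal = offset <= scenario.causal_snp < offset + k
        for name in ("mT", "mU", "fT", "fU"):
            if has_causal:
                haps[name][:, cols] = _haplotypes_given_causal(
                    rng, causal_alleles[name], k, scenario.causal_snp - offset,
                    a, t_thr)
            else:
                haps[name][:, cols] = _haplotypes_unconditional(rng, n, k, a, t_thr)
        offset += k

    mother = haps["mT"] + haps["mU"]
    father = haps["fT"] + haps["fU"]
    child = haps["mT"] + haps["fT"]

    kinds = np.concatenate([
        np.full(scenario.n_triads, FamilyKind.TRIAD, dtype=np.int8),
        np.full(scenario.n_case_mother_dyads, FamilyKind.CASE_MOTHER_DYAD, dtype=np.int8),
        np.full(scenario.n_case_father_dyads, FamilyKind.CASE_FATHER_DYAD, dtype=np.int8),
    ])
    rng.shuffle(kinds)
    father[kinds == FamilyKind.CASE_MOTHER_DYAD] = MISSING
    mother[kinds == FamilyKind.CASE_FATHER_DYAD] = MISSING

    active = exposed.copy()
    active[rng.random(n) < scenario.missing_exposure_rate] = MISSING
    passive_prev = (scenario.folate_prevalence if scenario.exposure == "smoking"
                    else scenario.smoking_prevalence)
    passive = rng.binomial(1, passive_prev, size=n).astype(np.int8)
    smoking, folate = (active, passive) if scenario.exposure == "smoking" \
        else (passive, active)

    sex = np.where(rng.random(n) < scenario.male_fraction, SEX_MALE, SEX_FEMALE
                   ).astype(np.int8)

    snps = _snp_table(scenario)
    cohort = Cohort(
        family_id=np.array([f"F{i + 1:05d}" for i in range(n)], dtype=object),
        family_kind=kinds,
        mother_gt=mother,
        father_gt=father,
        child_gt=child,
        smoking=smoking,
        folate=folate,
        subtype=subtype,
        child_sex=sex,
        snps=snps,
    )
    cohort.snps["maf"] = cohort.parental_allele_freq()
    return cohort
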