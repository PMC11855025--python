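"""Conditional log-linear likelihood for case-parent triads and dyads.

Model
-----
Conditioning on the child being affected, a family's origin-resolved
genotype configuration (mother dose ``m``, father dose ``f``, maternally and
paternally transmitted minor-allele indicators ``a_m``, ``a_f``) follows a
multinomial over 16 categories with

    P(cat | affected) ∝ π(m; q) π(f; q) τ(a_m|m) τ(a_f|f)
                        × Rm^m × Rcm^a_m × Rcf^a_f

where π is the Hardy–Weinberg genotype frequency at minor-allele frequency
``q``, τ is the Mendelian transmission probability (½ for a heterozygous
parent, 1 otherwise), ``Rm`` is the maternal per-allele relative risk, and
``Rcm``/``Rcf`` are the relative risks of a maternally/paternally inherited
minor allele.  The baseline disease risk cancels in the conditional form.
A plain child-dose model sets ``Rcm = Rcf = Rc``; the parent-of-origin (PoO)
estimand is the relative-risk ratio ``RRR = Rcm / Rcf``.

Missing parents (dyads) and the origin-ambiguous double-heterozygote triad
are handled by exact marginalization: the family likelihood sums the category
probabilities over every configuration compatible with the observed data.
This yields the same maximizer as an EM treatment of the missing data, with
a simpler convergence contract.

``ModelSpec(conditional_on_parents=True)`` instead conditions each complete
triad on the parental genotype pair (mating type).  Under that conditioning
the nuisance ``q`` drops out and, for the multiplicative child model, the MLE
is the classical TDT transmission ratio T/NT from heterozygous parents.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .families import MISSING, Cohort

logger = logging.getLogger(__name__)

VALID_EFFECTS = ("child_dose", "maternal_dose", "poo")


def _build_categories():
    rows = []
    for m, am_opts in ((0, (0,)), (1, (0, 1)), (2, (1,))):
        for am in am_opts:
            for f, af_opts in ((0, (0,)), (1, (0, 1)), (2, (1,))):
                for af in af_opts:
                    rows.append((m, f, am, af))
    arr = np.array(rows, dtype=np.int64)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


#: the 16 origin-resolved categories, fixed module-wide order
CAT_M, CAT_F, CAT_AM, CAT_AF = _build_categories()
CAT_C = CAT_AM + CAT_AF
N_CATEGORIES = 16
#: log Mendelian transmission factor per category
_LOG_TAU = np.where(CAT_M == 1, np.log(0.5), 0.0) + np.where(CAT_F == 1, np.log(0.5), 0.0)


def enumerate_origin_categories() -> pd.DataFrame:
    """The 16 origin-resolved triad categories in model order.

    Columns ``m, f, a_m, a_f, c``; the observable (m, f, c) triples number 15,
    with (1, 1, 1) the only origin-ambiguous one.
    """
    return pd.DataFrame(
        {"m": CAT_M, "f": CAT_F, "a_m": CAT_AM, "a_f": CAT_AF, "c": CAT_C}
    )


def origin_prior(q: float) -> np.ndarray:
    """HWE × random-mating × Mendelian prior over the 16 categories."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"allele frequency q={q} outside (0, 1)")
    log_hwe = np.log([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    return np.exp(log_hwe[CAT_M] + log_hwe[CAT_F] + _LOG_TAU)


@dataclass(frozen=True)
class ModelSpec:
    """Which relative-risk effects are estimated.

    ``effects`` is a subset of {'child_dose', 'maternal_dose', 'poo'};
    'child_dose' and 'poo' are mutually exclusive parameterizations of the
    child allele effect ('poo' splits it by parental origin).
    ``conditional_on_parents`` switches to the mating-type-conditioned
    likelihood (complete triads only; no allele-frequency nuisance).
    """

    effects: tuple = ("child_dose",)
    conditional_on_parents: bool = False

    def __post_init__(self):
        eff = tuple(self.effects)
        object.__setattr__(self, "effects", eff)
        unknown = set(eff) - set(VALID_EFFECTS)
        if unknown:
            raise ValueError(f"unknown effects {sorted(unknown)}")
        if len(set(eff)) != len(eff):
            raise ValueError("duplicate effects")
        if "child_dose" in eff and "poo" in eff:
            raise ValueError("'child_dose' and 'poo' are mutually exclusive")
        if not eff:
            raise ValueError("at least one effect is required")

    @property
    def free_param_names(self) -> tuple:
        names = [] if self.conditional_on_parents else ["logit_q"]
        if "child_dose" in self.effects:
            names.append("log_rc")
        if "maternal_dose" in self.effects:
            names.append("log_rm")
        if "poo" in self.effects:
            names += ["log_rcm", "log_rcf"]
        return tuple(names)


@dataclass
class ParamVector:
    """Model parameters on the natural scale (log relative risks, q)."""

    q: float = 0.5
    log_rc: float = 0.0
    log_rm: float = 0.0
    log_rcm: float = 0.0
    log_rcf: float = 0.0

    @property
    def rr_child(self) -> float:
        return float(np.exp(self.log_rc))

    @property
    def rr_maternal(self) -> float:
        return float(np.exp(self.log_rm))

    @property
    def rrr(self) -> float:
        """PoO relative-risk ratio Rcm / Rcf."""
        return float(np.exp(self.log_rcm - self.log_rcf))


def _transmission_log_risks(params: ParamVector, spec: ModelSpec):
    """Per-origin log relative risks (lcm, lcf) implied by the spec."""
    if "poo" in spec.effects:
        return params.log_rcm, params.log_rcf
    if "child_dose" in spec.effects:
        return params.log_rc, params.log_rc
    return 0.0, 0.0


def category_log_weights(params: ParamVector, spec: ModelSpec) -> np.ndarray:
    """Unnormalized log P(cat | affected) over the 16 categories."""
    lcm, lcf = _transmission_log_risks(params, spec)
    lrm = params.log_rm if "maternal_dose" in spec.effects else 0.0
    lw = CAT_M * lrm + CAT_AM * lcm + CAT_AF * lcf
    if spec.conditional_on_parents:
        return _LOG_TAU + lw
    return np.log(origin_prior(params.q)) + lw


def category_probability(params: ParamVector, spec: ModelSpec = ModelSpec()) -> np.ndarray:
    """P(category | affected child): normalized over the 16 categories."""
    lw = category_log_weights(params, spec)
    w = np.exp(lw - lw.max())
    return w / w.sum()


# ---------------------------------------------------------------------------
# observation patterns
# ---------------------------------------------------------------------------

class PatternCounts:
    """Aggregated (m, f, c) observation patterns for one SNP and family set.

    Families sharing the same observed pattern contribute identical likelihood
    terms, so the likelihood reduces to a weighted sum over unique patterns.
    ``compat[p, k]`` marks category ``k`` compatible with pattern ``p``
    (missing parental doses marginalize); for the mating-type-conditioned
    likelihood ``parent_group[p, k]`` marks categories sharing pattern p's
    parental pair.
    """

    def __init__(self, m: np.ndarray, f: np.ndarray, c: np.ndarray):
        m = np.asarray(m, dtype=int)
        f = np.asarray(f, dtype=int)
        c = np.asarray(c, dtype=int)
        keep = c != MISSING
        self.n_child_missing = int((~keep).sum())
        trip = np.stack([m[keep], f[keep], c[keep]], axis=1)
        if len(trip):
            pats, counts = np.unique(trip, axis=0, return_counts=True)
        else:
            pats, counts = np.zeros((0, 3), int), np.zeros(0, int)
        compat = (
            ((pats[:, [0]] == MISSING) | (pats[:, [0]] == CAT_M[None, :]))
            & ((pats[:, [1]] == MISSING) | (pats[:, [1]] == CAT_F[None, :]))
            & (pats[:, [2]] == CAT_C[None, :])
        )
        # Mendelian-impossible patterns have no compatible category
        possible = compat.any(axis=1)
        self.n_mendelian_excluded = int(counts[~possible].sum())
        self.patterns = pats[possible]
        self.counts = counts[possible].astype(float)
        self.compat = compat[possible]
        self.parent_group = (
            (self.patterns[:, [0]] == CAT_M[None, :])
            & (self.patterns[:, [1]] == CAT_F[None, :])
        )
        self.all_parents_observed = bool(
            (self.patterns[:, :2] != MISSING).all() if len(self.patterns) else True
        )

    @property
    def n_families(self) -> int:
        return int(self.counts.sum())


def _features(spec: ModelSpec, q: float) -> np.ndarray:
    """Per-category score features, columns ordered as free_param_names.

    d log w / d logit(q) = (m - 2q) + (f - 2q) for the HWE prior.
    """
    cols = []
    if not spec.conditional_on_parents:
        cols.append(CAT_M + CAT_F - 4.0 * q)
    if "child_dose" in spec.effects:
        cols.append((CAT_AM + CAT_AF).astype(float))
    if "maternal_dose" in spec.effects:
        cols.append(CAT_M.astype(float))
    if "poo" in spec.effects:
        cols.append(CAT_AM.astype(float))
        cols.append(CAT_AF.astype(float))
    return np.column_stack(cols)


def _params_from_x(x: np.ndarray, spec: ModelSpec, q_fixed: float = 0.5) -> ParamVector:
    params = ParamVector(q=q_fixed)
    for name, val in zip(spec.free_param_names, x):
        if name == "logit_q":
            params.q = float(expit(val))
        else:
            setattr(params, name, float(val))
    return params


def _negloglik_and_grad(x: np.ndarray, pats: PatternCounts, spec: ModelSpec):
    params = _params_from_x(x, spec)
    lw = category_log_weights(params, spec)
    w = np.exp(lw - lw.max())
    X = _features(spec, params.q)
    S = pats.compat @ w
    wX = w[:, None] * X
    num = pats.compat @ wX  # (P, p) d S_p / d theta
    if spec.conditional_on_parents:
        Z = pats.parent_group @ w
        dZ = pats.parent_group @ wX
        ll = pats.counts @ (np.log(S) - np.log(Z))
        grad = pats.counts @ (num / S[:, None] - dZ / Z[:, None])
    else:
        Z = w.sum()
        dZ = wX.sum(axis=0)
        n = pats.counts.sum()
        ll = pats.counts @ np.log(S) - n * np.log(Z)
        grad = pats.counts @ (num / S[:, None]) - n * dZ / Z
    return -ll, -grad


def _numerical_hessian(fun_grad, x: np.ndarray, pats, spec, h: float = 1e-5) -> np.ndarray:
    p = len(x)
    H = np.zeros((p, p))
    for j in range(p):
        step = h * (1.0 + abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += step
        xm[j] -= step
        _, gp = fun_grad(xp, pats, spec)
        _, gm = fun_grad(xm, pats, spec)
        H[:, j] = (gp - gm) / (2 * step)
    return 0.5 * (H + H.T)


@dataclass
class FitResult:
    """MLE of one SNP × family-set fit."""

    spec: ModelSpec
    param_names: tuple
    x: np.ndarray
    params: ParamVector
    cov: np.ndarray
    loglik: float
    n_families_used: int
    n_mendelian_excluded: int
    converged: bool
    n_iter: int

    def estimate(self, name: str) -> float:
        return float(self.x[self.param_names.index(name)])

    def se(self, name: str) -> float:
        j = self.param_names.index(name)
        v = self.cov[j, j]
        return float(np.sqrt(v)) if np.isfinite(v) and v >= 0 else np.inf

    def effect_estimate(self, effect: str):
        """(log-scale estimate, SE) of a named effect.

        'poo' returns the log relative-risk ratio log Rcm − log Rcf with its
        delta-method SE from the joint covariance.
        """
        if effect == "poo":
            i = self.param_names.index("log_rcm")
            j = self.param_names.index("log_rcf")
            est = float(self.x[i] - self.x[j])
            var = self.cov[i, i] + self.cov[j, j] - 2 * self.cov[i, j]
            se = float(np.sqrt(var)) if np.isfinite(var) and var >= 0 else np.inf
            return est, se
        name = {"child_dose": "log_rc", "maternal_dose": "log_rm"}[effect]
        return self.estimate(name), self.se(name)


def _start_point(pats: PatternCounts, spec: ModelSpec) -> np.ndarray:
    x0 = []
    if not spec.conditional_on_parents:
        # parental allele frequency; fall back to children if no parent typed
        num = den = 0.0
        for (m, f, _), cnt in zip(pats.patterns, pats.counts):
            for d in (m, f):
                if d != MISSING:
                    num += cnt * d
                    den += 2 * cnt
        if den == 0:
            num = float(pats.counts @ pats.patterns[:, 2])
            den = 2.0 * pats.counts.sum()
        q0 = min(max(num / den, 0.02), 0.98) if den else 0.5
        x0.append(logit(q0))
    x0 += [0.0] * (len(spec.free_param_names) - len(x0))
    return np.array(x0)


def fit_patterns(pats: PatternCounts, spec: ModelSpec,
                 gtol: float = 1e-8, maxiter: int = 200) -> FitResult:
    """Maximize the pattern likelihood by quasi-Newton ascent from the null."""
    names = spec.free_param_names
    p = len(names)
    if spec.conditional_on_parents and not pats.all_parents_observed:
        raise ValueError("mating-type-conditioned fit requires complete triads")
    if pats.n_families == 0:
        return FitResult(spec, names, np.full(p, np.nan), ParamVector(np.nan),
                         np.full((p, p), np.inf), np.nan, 0,
                         pats.n_mendelian_excluded, False, 0)
    x0 = _start_point(pats, spec)
    res = minimize(_negloglik_and_grad, x0, args=(pats, spec), jac=True,
                   method="BFGS", options={"gtol": gtol, "maxiter": maxiter})
    _, g = _negloglik_and_grad(res.x, pats, spec)
    boundary = bool(np.any(np.abs(res.x) > 12.0))
    converged = (res.success or float(np.max(np.abs(g))) < 1e-5) and not boundary
    cov = np.full((p, p), np.inf)
    if converged:
        H = _numerical_hessian(_negloglik_and_grad, res.x, pats, spec)
        try:
            cov_try = np.linalg.inv(H)
            if np.all(np.isfinite(cov_try)) and np.all(np.diag(cov_try) > 0):
                cov = cov_try
            else:
                converged = False
        except np.linalg.LinAlgError:
            converged = False
    params = _params_from_x(res.x, spec)
    return FitResult(spec, names, res.x, params, cov, -float(res.fun),
                     pats.n_families, pats.n_mendelian_excluded,
                     converged, int(res.nit))


def snp_patterns(cohort: Cohort, snp: int | str,
                 family_mask: np.ndarray | None = None) -> PatternCounts:
    """Observation patterns for one SNP over (a subset of) the cohort."""
    j = snp if isinstance(snp, (int, np.integer)) else \
        int(cohort.snps.index[cohort.snps["snp_id"] == snp][0])
    if family_mask is None:
        family_mask = np.ones(cohort.n_families, dtype=bool)
    return PatternCounts(
        cohort.mother_gt[family_mask, j],
        cohort.father_gt[family_mask, j],
        cohort.child_gt[family_mask, j],
    )


def fit_model(cohort: Cohort, snp: int | str, spec: ModelSpec,
              family_mask: np.ndarray | None = None, **kw) -> FitResult:
    """Fit one SNP on (a subset of) the cohort; see :func:`fit_patterns`."""
    pats = snp_patterns(cohort, snp, family_mask)
    if pats.n_mendelian_excluded:
        logger.warning("SNP %s: excluded %d Mendelian-inconsistent famil(ies)",
                       snp, pats.n_mendelian_excluded)
    return fit_patterns(pats, spec, **kw)


# ---------------------------------------------------------------------------
# family-level likelihood (reference path; the fitter uses PatternCounts)
# ---------------------------------------------------------------------------

def family_loglik(mother: int, father: int, child: int,
                  params: ParamVector, spec: ModelSpec = ModelSpec()) -> float:
    """Log-likelihood of one family's observed doses at one SNP.

    Sums conditional category probabilities over every origin-resolved
    configuration compatible with the (possibly partial) observation; a
    Mendelian-impossible complete triad returns ``-inf``.
    """
    if child == MISSING:
        raise ValueError("case child genotype must be observed")
    probs = category_probability(params, spec)
    ok = (
        ((mother == MISSING) | (CAT_M == mother))
        & ((father == MISSING) | (CAT_F == father))
        & (CAT_C == child)
    )
    s = probs[ok].sum()
    return float(np.log(s)) if s > 0 else -np.inf


def cohort_loglik(cohort: Cohort, snp: int | str, params: ParamVector,
                  spec: ModelSpec = ModelSpec()) -> float:
    pats = snp_patterns(cohort, snp)
    nll, _ = _negloglik_and_grad(
        np.array([getattr(params, n) if n != "logit_q" else logit(params.q)
                  for n in spec.free_param_names]),
        pats, spec)
    return -float(nll)


# ---------------------------------------------------------------------------
# closed forms for the multiplicative child model (test oracles)
# ---------------------------------------------------------------------------

def tdt_transmission_ratio(t: int, nt: int) -> float:
    """Classical TDT estimate T/NT of the child relative risk.

    Exact MLE of the multiplicative child model *conditioned on parental
    mating types* (complete triads).
    """
    return t / nt


def allele_odds_ratio(transmitted_minor: int, untransmitted_minor: int,
                      n_parents: int) -> float:
    """Closed-form MLE of the child relative risk under the HWE likelihood.

    On complete triads the HWE conditional likelihood factorizes over the four
    parental alleles: untransmitted alleles are Bernoulli(q) and transmitted
    alleles Bernoulli(qRc / (1 − q + qRc)), so the MLE of Rc is the odds ratio
    of minor-allele counts among transmitted vs untransmitted alleles.
    """
    t, u, n = transmitted_minor, untransmitted_minor, n_parents
    return (t / (n - t)) / (u / (n - u))
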