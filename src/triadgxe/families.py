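"""Case-parent family data: cohort container, validation and summaries.

The unit of observation is a *case family*: an affected child together with
one or both genotyped biological parents.  Complete families are triads;
families missing the father (mother) are case-mother (case-father) dyads.
Genotypes are stored as minor-allele dose in {0, 1, 2}, with ``MISSING``
(-1) for untyped individuals/sites.  Binary maternal exposures (periconceptional
smoking, folic-acid supplementation) and the orofacial-cleft subtype
(CL/P vs CPO) are carried per family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for missing genotype dose / exposure / subtype / sex codes
MISSING: int = -1


class FamilyKind(IntEnum):
    """Which members of the family are genotyped."""

    TRIAD = 0
    CASE_MOTHER_DYAD = 1
    CASE_FATHER_DYAD = 2


#: subtype codes: cleft lip with/without palate, cleft palate only
SUBTYPE_CLP: int = 0
SUBTYPE_CPO: int = 1
SUBTYPE_LABELS = {SUBTYPE_CLP: "CLP", SUBTYPE_CPO: "CPO", MISSING: "missing"}
SUBTYPE_CODES = {"CLP": SUBTYPE_CLP, "CPO": SUBTYPE_CPO}

#: PED sex codes
SEX_MALE: int = 1
SEX_FEMALE: int = 2


@dataclass
class FamilyRecord:
    """One case family with per-SNP genotype doses and covariates."""

    family_id: str
    kind: FamilyKind
    mother_gt: np.ndarray
    father_gt: np.ndarray
    child_gt: np.ndarray
    smoking: int = MISSING
    folate: int = MISSING
    subtype: int = MISSING
    child_sex: int = MISSING

    @property
    def n_members(self) -> int:
        return 3 if self.kind == FamilyKind.TRIAD else 2


@dataclass
class Cohort:
    """A collection of case families, column-aligned across SNPs.

    Genotype matrices have shape ``(n_families, n_snps)`` (dtype int8,
    ``MISSING`` = -1).  ``snps`` is a DataFrame with columns
    ``snp_id, chrom, pos, minor, other, maf, imputed`` in the same column
    order as the genotype matrices.
    """

    family_id: np.ndarray
    family_kind: np.ndarray
    mother_gt: np.ndarray
    father_gt: np.ndarray
    child_gt: np.ndarray
    smoking: np.ndarray
    folate: np.ndarray
    subtype: np.ndarray
    child_sex: np.ndarray
    snps: pd.DataFrame = field(default_factory=lambda: _empty_snps())

    def __post_init__(self) -> None:
        n = len(self.family_id)
        k = len(self.snps)
        for name in ("mother_gt", "father_gt", "child_gt"):
            g = np.asarray(getattr(self, name), dtype=np.int8).reshape(n, k)
            setattr(self, name, g)
        for name in ("family_kind", "smoking", "folate", "subtype", "child_sex"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int8).reshape(n))
        self.family_id = np.asarray(self.family_id, dtype=object).reshape(n)
        self.snps = self.snps.reset_index(drop=True)

    # -- basic bookkeeping -------------------------------------------------
    @property
    def n_families(self) -> int:
        return len(self.family_id)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_triads(self) -> int:
        return int(np.sum(self.family_kind == FamilyKind.TRIAD))

    @property
    def n_dyads(self) -> int:
        return int(np.sum(self.family_kind != FamilyKind.TRIAD))

    @property
    def n_individuals(self) -> int:
        """Genotyped individuals: 3 per triad + 2 per dyad."""
        return 3 * self.n_triads + 2 * self.n_dyads

    def family(self, i: int) -> FamilyRecord:
        return FamilyRecord(
            family_id=str(self.family_id[i]),
            kind=FamilyKind(int(self.family_kind[i])),
            mother_gt=self.mother_gt[i],
            father_gt=self.father_gt[i],
            child_gt=self.child_gt[i],
            smoking=int(self.smoking[i]),
            folate=int(self.folate[i]),
            subtype=int(self.subtype[i]),
            child_sex=int(self.child_sex[i]),
        )

    def __iter__(self):
        return (self.family(i) for i in range(self.n_families))

    def __len__(self) -> int:
        return self.n_families

    # -- subsetting --------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return Cohort(
            family_id=self.family_id[idx],
            family_kind=self.family_kind[idx],
            mother_gt=self.mother_gt[idx],
            father_gt=self.father_gt[idx],
            child_gt=self.child_gt[idx],
            smoking=self.smoking[idx],
            folate=self.folate[idx],
            subtype=self.subtype[idx],
            child_sex=self.child_sex[idx],
            snps=self.snps.copy(),
        )

    def exposure(self, name: str) -> np.ndarray:
        if name not in ("smoking", "folate"):
            raise ValueError(f"unknown exposure {name!r}; expected 'smoking' or 'folate'")
        return getattr(self, name)

    # -- genotype views ----------------------------------------------------
    def parent_doses(self) -> np.ndarray:
        """Stacked parental dose matrix (mothers then fathers), NaN for missing.

        Parents are the founders of the design; allele frequencies and LD are
        estimated from them because the case children are ascertained.
        """
        out = np.vstack([self.mother_gt, self.father_gt]).astype(float)
        out[out == MISSING] = np.nan
        return out

    def parental_allele_freq(self) -> np.ndarray:
        """Per-SNP minor-allele frequency among genotyped parents."""
        d = self.parent_doses()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0


def _empty_snps() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["snp_id", "chrom", "pos", "minor", "other", "maf", "imputed"]
    )


def make_snp_table(
    snp_id, chrom, pos, minor, other, maf=np.nan, imputed=False
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": snp_id,
            "chrom": chrom,
            "pos": pos,
            "minor": minor,
            "other": other,
            "maf": maf,
            "imputed": imputed,
        }
    )


# ---------------------------------------------------------------------------
# allele orientation
# ---------------------------------------------------------------------------

def orient_to_minor(cohort: Cohort) -> Cohort:
    """Orient doses so they count the cohort-minor allele at every SNP.

    The minor allele is defined from *parental* genotypes only (cases are
    ascertained, parents approximate the source population).  A tie at
    frequency 0.5 is broken deterministically: the lexicographically smaller
    allele string is declared minor.  Idempotent.
    """
    freq = cohort.parental_allele_freq()
    snps = cohort.snps.copy()
    flip = np.zeros(cohort.n_snps, dtype=bool)
    for j in range(cohort.n_snps):
        f = freq[j]
        if np.isnan(f):
            continue
        if f > 0.5:
            flip[j] = True
        elif f == 0.5:
            a, b = str(snps.at[j, "minor"]), str(snps.at[j, "other"])
            flip[j] = a > b
    mats = {}
    for name in ("mother_gt", "father_gt", "child_gt"):
        g = getattr(cohort, name).copy()
        obs = g != MISSING
        for j in np.flatnonzero(flip):
            g[obs[:, j], j] = 2 - g[obs[:, j], j]
        mats[name] = g
    for j in np.flatnonzero(flip):
        snps.at[j, "minor"], snps.at[j, "other"] = (
            snps.at[j, "other"],
            snps.at[j, "minor"],
        )
    out = replace(cohort, snps=snps, **mats)
    out.snps["maf"] = out.parental_allele_freq()
    return out


# ---------------------------------------------------------------------------
# Mendelian validation
# ---------------------------------------------------------------------------

def _legal_triples() -> set:
    """All (m, f, c) dose triples possible under Mendelian transmission.

    Brute force: each parent transmits one of its alleles; a heterozygote may
    transmit either.
    """
    legal = set()
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    for m in (0, 1, 2):
        for f in (0, 1, 2):
            for am in alleles[m]:
                for af in alleles[f]:
                    legal.add((m, f, am + af))
    return legal


_LEGAL = _legal_triples()


def is_mendelian_consistent(m: int, f: int, c: int) -> bool:
    """Whether an (m, f, c) dose triple is possible; MISSING marginalizes."""
    ms = (0, 1, 2) if m == MISSING else (m,)
    fs = (0, 1, 2) if f == MISSING else (f,)
    return any((mi, fi, c) in _LEGAL for mi in ms for fi in fs)


def validate_mendelian(cohort: Cohort) -> pd.DataFrame:
    """Flag (family, SNP) pairs impossible under Mendelian transmission.

    Report-only: returns a DataFrame with columns
    ``family_id, snp_id, mother_gt, father_gt, child_gt``.
    """
    rows = []
    snp_ids = cohort.snps["snp_id"].to_numpy()
    for i in range(cohort.n_families):
        for j in range(cohort.n_snps):
            c = int(cohort.child_gt[i, j])
            if c == MISSING:
                continue
            m = int(cohort.mother_gt[i, j])
            f = int(cohort.father_gt[i, j])
            if not is_mendelian_consistent(m, f, c):
                rows.append((cohort.family_id[i], snp_ids[j], m, f, c))
    return pd.DataFrame(
        rows, columns=["family_id", "snp_id", "mother_gt", "father_gt", "child_gt"]
    )


def apply_mendelian_policy(
    cohort: Cohort, violations: pd.DataFrame, policy: str = "mask"
) -> Cohort:
    """Resolve flagged pairs.

    policy='mask' (default, conservative): set the offending parental dose to
    MISSING for that SNP — a parent is offending when its dose is impossible
    against the child alone; if neither parent is individually impossible the
    pair is jointly impossible and both are masked.
    policy='exclude': drop the whole family.
    """
    if policy not in ("mask", "exclude"):
        raise ValueError("policy must be 'mask' or 'exclude'")
    if violations.empty:
        return cohort
    fam_pos = {fid: i for i, fid in enumerate(cohort.family_id)}
    snp_pos = {sid: j for j, sid in enumerate(cohort.snps["snp_id"])}
    if policy == "exclude":
        bad = {fam_pos[f] for f in violations["family_id"]}
        keep = np.array([i not in bad for i in range(cohort.n_families)])
        return cohort.subset(keep)
    mother = cohort.mother_gt.copy()
    father = cohort.father_gt.copy()
    for _, row in violations.iterrows():
        i, j = fam_pos[row["family_id"]], snp_pos[row["snp_id"]]
        m, f, c = int(mother[i, j]), int(father[i, j]), int(cohort.child_gt[i, j])
        m_bad = m != MISSING and not is_mendelian_consistent(m, MISSING, c)
        f_bad = f != MISSING and not is_mendelian_consistent(MISSING, f, c)
        if not (m_bad or f_bad):
            m_bad = f_bad = True  # jointly impossible only
        if m_bad:
            mother[i, j] = MISSING
        if f_bad:
            father[i, j] = MISSING
    return replace(cohort, mother_gt=mother, father_gt=father)


# ---------------------------------------------------------------------------
# summaries and filters
# ---------------------------------------------------------------------------

def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Cohort characteristics by subtype stratum (Table-1-style).

    Returns a tidy DataFrame with one row per (stratum, variable):
    ``stratum`` in {'all', 'CLP', 'CPO'}, ``n`` the count, ``pct`` the
    percentage of the stratum's *full* family count (families with a missing
    value stay in the denominator; their count is reported as a separate
    ``variable`` suffixed ``_missing``).
    """
    strata = {
        "all": np.ones(cohort.n_families, dtype=bool),
        "CLP": cohort.subtype == SUBTYPE_CLP,
        "CPO": cohort.subtype == SUBTYPE_CPO,
    }
    rows = []
    for label, mask in strata.items():
        denom = int(mask.sum())
        def add(variable, count):
            pct = 100.0 * count / denom if denom else np.nan
            rows.append((label, variable, int(count), pct, denom))
        add("families", denom)
        add("smoking", np.sum(mask & (cohort.smoking == 1)))
        add("smoking_missing", np.sum(mask & (cohort.smoking == MISSING)))
        add("folate", np.sum(mask & (cohort.folate == 1)))
        add("folate_missing", np.sum(mask & (cohort.folate == MISSING)))
        add("male", np.sum(mask & (cohort.child_sex == SEX_MALE)))
        add("female", np.sum(mask & (cohort.child_sex == SEX_FEMALE)))
        add("triads", np.sum(mask & (cohort.family_kind == FamilyKind.TRIAD)))
        add("dyads", np.sum(mask & (cohort.family_kind != FamilyKind.TRIAD)))
    return pd.DataFrame(rows, columns=["stratum", "variable", "n", "pct", "denominator"])


def filter_subtype(cohort: Cohort, subtype: str) -> Cohort:
    """Families of one orofacial-cleft subtype ('CLP' or 'CPO').

    Families with missing subtype are excluded from both strata.
    """
    if subtype not in SUBTYPE_CODES:
        raise ValueError(f"unknown subtype {subtype!r}; expected one of {sorted(SUBTYPE_CODES)}")
    return cohort.subset(cohort.subtype == SUBTYPE_CODES[subtype])
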