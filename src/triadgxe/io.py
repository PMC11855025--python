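"""Reading and writing cohort files: VCF genotypes, PED roles, covariate TSV.

File dialects
-------------
* VCF v4.2, biallelic autosomal SNPs; sample ids must match PED individual ids.
* 6-column PED/FAM: ``family_id individual_id father_id mother_id sex phenotype``
  with ``0`` meaning "no parent recorded", sex 1=male/2=female/0=unknown and
  affection code 2 = case.
* covariates: TSV with header ``family_id smoking folate subtype``; smoking and
  folate are 0/1 (blank or ``NA`` = missing), subtype is ``CLP``/``CPO``.
* regions: BED-like TSV ``chrom start end region_name`` (0-based half-open).
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .families import (
    MISSING,
    Cohort,
    FamilyKind,
    SUBTYPE_CODES,
    SUBTYPE_LABELS,
    make_snp_table,
    orient_to_minor,
)

logger = logging.getLogger(__name__)

PED_COLUMNS = ["family_id", "individual_id", "father_id", "mother_id", "sex", "phenotype"]


def read_pedigree(path: str) -> pd.DataFrame:
    ped = pd.read_csv(path, sep=r"\s+", header=None, names=PED_COLUMNS, dtype=str)
    ped["sex"] = ped["sex"].astype(int)
    ped["phenotype"] = ped["phenotype"].astype(int)
    dup = ped["individual_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate individual id(s) in pedigree: {sorted(ped.loc[dup, 'individual_id'])}"
        )
    return ped


def read_covariates(path: str) -> pd.DataFrame:
    cov = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "smoking", "folate", "subtype"}
    if not required.issubset(cov.columns):
        raise ValueError(f"covariate file must have columns {sorted(required)}")
    return cov


def read_regions(path: str) -> pd.DataFrame:
    reg = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "region_name"],
        dtype={"chrom": str}, comment="#",
    )
    reg["start"] = reg["start"].astype(int)
    reg["end"] = reg["end"].astype(int)
    return reg


def _read_vcf_matrix(vcf_path: str, strict: bool = False):
    """Dose matrix (n_samples, n_snps) of ALT dose, plus SNP metadata."""
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    doses, meta = [], []
    n_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            if strict:
                raise ValueError(f"multiallelic or non-SNP site at {var.CHROM}:{var.POS}")
            n_dropped += 1
            continue
        if samples:
            gt = np.array(var.genotypes, dtype=int)  # (n_samples, 3): a1, a2, phased
            dose = gt[:, 0] + gt[:, 1]
            dose[(gt[:, 0] < 0) | (gt[:, 1] < 0)] = MISSING
        else:
            dose = np.zeros(0, dtype=int)
        doses.append(dose.astype(np.int8))
        rid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        imputed = bool(var.INFO.get("IMPUTED", 0))
        meta.append((rid, var.CHROM, var.POS, var.ALT[0], var.REF, imputed))
    if n_dropped:
        logger.warning("dropped %d multiallelic/non-SNP site(s)", n_dropped)
    if meta:
        snp_id, chrom, pos, alt, ref, imputed = zip(*meta)
        snps = make_snp_table(list(snp_id), list(chrom), list(pos), list(alt), list(ref),
                              imputed=list(imputed))
        mat = np.column_stack(doses)
    else:
        snps = make_snp_table([], [], [], [], [])
        mat = np.zeros((len(samples), 0), dtype=np.int8)
    return samples, mat, snps


def _encode_exposure(value) -> int:
    if pd.isna(value) or str(value).upper() in ("", "NA", "."):
        return MISSING
    return int(value)


def read_cohort(
    vcf_path: str, pedigree_path: str, covariate_path: str | None = None,
    strict: bool = False, orient: bool = True,
) -> Cohort:
    """Assemble a :class:`Cohort` from VCF + PED (+ covariate TSV).

    One family per case child with at least one genotyped parent; other
    individuals are dropped with a logged count.  A parent listed in the
    pedigree but absent from the VCF demotes the family to a dyad.  Doses are
    oriented to count the cohort-minor allele (parental frequencies).
    """
    samples, mat, snps = _read_vcf_matrix(vcf_path, strict=strict)
    sample_pos = {s: i for i, s in enumerate(samples)}
    ped = read_pedigree(pedigree_path)
    cov = read_covariates(covariate_path) if covariate_path else None
    cov_map = {} if cov is None else {r["family_id"]: r for _, r in cov.iterrows()}

    k = len(snps)
    rows = {name: [] for name in
            ("family_id", "family_kind", "mother_gt", "father_gt", "child_gt",
             "smoking", "folate", "subtype", "child_sex")}
    n_dropped_families = 0
    used = set()
    for fam_id, group in ped.groupby("family_id", sort=True):
        cases = group[(group["phenotype"] == 2)]
        cases = cases[cases["individual_id"].isin(sample_pos)]
        if len(cases) == 0:
            logger.warning("family %s has no genotyped case child; dropped", fam_id)
            n_dropped_families += 1
            continue
        case = cases.iloc[0]
        if len(cases) > 1:
            logger.warning("family %s has %d cases; using %s",
                           fam_id, len(cases), case["individual_id"])

        def dose_of(ind_id):
            if ind_id in ("0", "", None) or ind_id not in sample_pos:
                return np.full(k, MISSING, dtype=np.int8)
            used.add(ind_id)
            return mat[sample_pos[ind_id]]

        mother = dose_of(case["mother_id"])
        father = dose_of(case["father_id"])
        used.add(case["individual_id"])
        has_m = (mother != MISSING).any() or (case["mother_id"] in sample_pos)
        has_f = (father != MISSING).any() or (case["father_id"] in sample_pos)
        if not (has_m or has_f):
            logger.warning("family %s: case child without any genotyped parent; dropped", fam_id)
            n_dropped_families += 1
            continue
        if has_m and has_f:
            kind = FamilyKind.TRIAD
        elif has_m:
            kind = FamilyKind.CASE_MOTHER_DYAD
            logger.warning("family %s: father not genotyped; treated as case-mother dyad", fam_id)
        else:
            kind = FamilyKind.CASE_FATHER_DYAD
            logger.warning("family %s: mother not genotyped; treated as case-father dyad", fam_id)

        c = cov_map.get(fam_id)
        rows["family_id"].append(fam_id)
        rows["family_kind"].append(int(kind))
        rows["mother_gt"].append(mother)
        rows["father_gt"].append(father)
        rows["child_gt"].append(mat[sample_pos[case["individual_id"]]])
        rows["smoking"].append(_encode_exposure(c["smoking"]) if c is not None else MISSING)
        rows["folate"].append(_encode_exposure(c["folate"]) if c is not None else MISSING)
        sub = MISSING
        if c is not None and isinstance(c["subtype"], str) and c["subtype"] in SUBTYPE_CODES:
            sub = SUBTYPE_CODES[c["subtype"]]
        rows["subtype"].append(sub)
        rows["child_sex"].append(int(case["sex"]) if int(case["sex"]) in (1, 2) else MISSING)

    n_unused = len(samples) - len(used)
    if n_unused:
        logger.info("%d genotyped individual(s) not part of any case family", n_unused)
    if n_dropped_families:
        logger.info("dropped %d famil(ies) without a usable case unit", n_dropped_families)

    n = len(rows["family_id"])
    cohort = Cohort(
        family_id=np.array(rows["family_id"], dtype=object),
        family_kind=np.array(rows["family_kind"], dtype=np.int8),
        mother_gt=(np.vstack(rows["mother_gt"]) if n else np.zeros((0, k), np.int8)),
        father_gt=(np.vstack(rows["father_gt"]) if n else np.zeros((0, k), np.int8)),
        child_gt=(np.vstack(rows["child_gt"]) if n else np.zeros((0, k), np.int8)),
        smoking=np.array(rows["smoking"], dtype=np.int8),
        folate=np.array(rows["folate"], dtype=np.int8),
        subtype=np.array(rows["subtype"], dtype=np.int8),
        child_sex=np.array(rows["child_sex"], dtype=np.int8),
        snps=snps,
    )
    return orient_to_minor(cohort) if orient else cohort


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_cohort(cohort: Cohort, prefix: str) -> dict:
    """Write ``<prefix>.vcf``, ``<prefix>.ped`` and ``<prefix>.cov.tsv``.

    REF is the other (major) allele and ALT the minor allele, so ALT dose in
    the VCF equals the stored minor-allele dose and a round trip through
    :func:`read_cohort` is exact.  Dyads omit the missing parent from both the
    VCF and the PED.
    """
    paths = {
        "vcf": f"{prefix}.vcf",
        "ped": f"{prefix}.ped",
        "cov": f"{prefix}.cov.tsv",
    }
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)

    sample_ids, sample_doses, ped_rows = [], [], []
    for i in range(cohort.n_families):
        fid = str(cohort.family_id[i])
        kind = FamilyKind(int(cohort.family_kind[i]))
        cid, mid, did = f"{fid}_c", f"{fid}_m", f"{fid}_f"
        has_m = kind in (FamilyKind.TRIAD, FamilyKind.CASE_MOTHER_DYAD)
        has_f = kind in (FamilyKind.TRIAD, FamilyKind.CASE_FATHER_DYAD)
        if has_m:
            sample_ids.append(mid)
            sample_doses.append(cohort.mother_gt[i])
            ped_rows.append((fid, mid, "0", "0", 2, 1))
        if has_f:
            sample_ids.append(did)
            sample_doses.append(cohort.father_gt[i])
            ped_rows.append((fid, did, "0", "0", 1, 1))
        sample_ids.append(cid)
        sample_doses.append(cohort.child_gt[i])
        sex = int(cohort.child_sex[i])
        ped_rows.append((fid, cid, did if has_f else "0", mid if has_m else "0",
                         sex if sex in (1, 2) else 0, 2))

    doses = (np.vstack(sample_doses) if sample_ids
             else np.zeros((0, cohort.n_snps), np.int8))
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=IMPUTED,Number=0,Type=Flag,Description="Imputed site">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(cohort.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
        # a sample-less VCF has no FORMAT column
        fh.write(("\tFORMAT\t" + "\t".join(sample_ids) if sample_ids else "") + "\n")
        for j, snp in cohort.snps.iterrows():
            info = "IMPUTED" if snp["imputed"] else "."
            gts = "\t".join(_GT_STR[int(d)] for d in doses[:, j])
            fh.write(
                f"{snp['chrom']}\t{int(snp['pos'])}\t{snp['snp_id']}\t"
                f"{snp['other']}\t{snp['minor']}\t.\tPASS\t{info}"
                + (f"\tGT\t{gts}" if sample_ids else "") + "\n"
            )

    with open(paths["ped"], "w") as fh:
        for row in ped_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    cov = pd.DataFrame(
        {
            "family_id": cohort.family_id,
            "smoking": [x if x != MISSING else "NA" for x in cohort.smoking],
            "folate": [x if x != MISSING else "NA" for x in cohort.folate],
            "subtype": [SUBTYPE_LABELS[int(s)] if int(s) != MISSING else "NA"
                        for s in cohort.subtype],
        }
    )
    cov.to_csv(paths["cov"], sep="\t", index=False)
    return paths


def write_regions(regions: pd.DataFrame, path: str) -> str:
    regions[["chrom", "start", "end", "region_name"]].to_csv(
        path, sep="\t", index=False, header=False
    )
    return path
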