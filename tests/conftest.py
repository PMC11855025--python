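import numpy as np
import pytest

import triadgxe as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def null_triads():
    """2000 complete triads under the null (all relative risks 1)."""
    sc = tg.Scenario(n_triads=2000, n_case_mother_dyads=0, n_case_father_dyads=0,
                     missing_exposure_rate=0.0)
    return tg.simulate_cohort(sc, seed=42)


@pytest.fixture
def margins_cohort():
    return tg.study_margins_cohort()


def write_mini_trio_files(tmp_path, drop_father=False):
    """One family (mother M1, father D1, child C1), two SNPs."""
    samples = ["M1", "C1"] if drop_father else ["M1", "D1", "C1"]
    gts = {
        "M1": ["0/1", "0/0"],
        "D1": ["0/0", "0/1"],
        "C1": ["0/1", "0/1"],
    }
    vcf = tmp_path / "mini.vcf"
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for j, (pos, rid) in enumerate([(100, "rs1"), (200, "rs2")]):
        row = f"1\t{pos}\t{rid}\tG\tA\t.\tPASS\t.\tGT"
        for s in samples:
            row += "\t" + gts[s][j]
        lines.append(row)
    vcf.write_text("\n".join(lines) + "\n")
    ped = tmp_path / "mini.ped"
    ped.write_text("FAM1\tM1\t0\t0\t2\t1\nFAM1\tD1\t0\t0\t1\t1\nFAM1\tC1\tD1\tM1\t1\t2\n")
    cov = tmp_path / "mini.cov.tsv"
    cov.write_text("family_id\tsmoking\tfolate\tsubtype\nFAM1\t1\t0\tCLP\n")
    return str(vcf), str(ped), str(cov)
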