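"""End-to-end orchestration: (simulate |) read -> scan -> pool -> report."""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import tempfile
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .families import Cohort, filter_subtype, summarize_cohort, validate_mendelian, \
    apply_mendelian_policy
from .inference import gxe_scan
from .io import read_cohort, read_regions
from .pooling import pool_regions
from .simulate import Scenario, scenario_regions, simulate_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration; serialized into output metadata."""

    effect: str = "maternal"
    exposure: str = "smoking"
    vcf: str | None = None
    ped: str | None = None
    cov: str | None = None
    regions: str | None = None
    scenario: Scenario | None = None
    subtype: str | None = None
    maternal_only: bool = False
    mendelian_policy: str = "mask"
    alpha: float = 0.05
    pooling_B: int = 10_000
    seed: int = 0
    out_prefix: str = "triadgxe_run"

    def __post_init__(self):
        if self.effect not in ("maternal", "poo"):
            raise ValueError("effect must be 'maternal' or 'poo'")
        if self.exposure not in ("smoking", "folate"):
            raise ValueError("exposure must be 'smoking' or 'folate'")
        have_files = all(p is not None for p in (self.vcf, self.ped))
        if not have_files and self.scenario is None:
            raise ValueError("provide either vcf+ped inputs or a scenario")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def to_json_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.scenario is not None:
            d["scenario"] = dataclasses.asdict(self.scenario)
        return d


def _atomic_write(df: pd.DataFrame, path: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    os.makedirs(d, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    os.close(fd)
    try:
        df.to_csv(tmp, sep="\t", index=False, float_format="%.12g")
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.remove(tmp)
        raise


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns a bundle of output paths and tables.

    Writes ``<prefix>.scan.tsv`` (per-SNP interaction tests),
    ``<prefix>.region.tsv`` (pooled region p-values with the Bonferroni
    threshold), ``<prefix>.summary.tsv`` (cohort characteristics) and
    ``<prefix>.meta.json`` (config, seeds, package version).  Outputs are
    written atomically; any failure removes partial outputs.
    """
    written = []
    try:
        if config.scenario is not None and config.vcf is None:
            cohort = simulate_cohort(config.scenario, config.seed)
            regions = scenario_regions(config.scenario)
        else:
            cohort = read_cohort(config.vcf, config.ped, config.cov)
            if config.regions is None:
                raise ValueError("a regions file is required with file inputs")
            regions = read_regions(config.regions)
        viol = validate_mendelian(cohort)
        if len(viol):
            logger.warning("%d Mendelian-inconsistent (family, SNP) pair(s); policy=%s",
                           len(viol), config.mendelian_policy)
            cohort = apply_mendelian_policy(cohort, viol, config.mendelian_policy)
        if config.subtype:
            cohort = filter_subtype(cohort, config.subtype)

        summary = summarize_cohort(cohort)
        scan = gxe_scan(cohort, config.effect, config.exposure,
                        maternal_only=config.maternal_only)
        region_table = pool_regions(scan, regions, cohort, B=config.pooling_B,
                                    seed=config.seed, alpha=config.alpha)

        paths = {
            "scan": f"{config.out_prefix}.scan.tsv",
            "region": f"{config.out_prefix}.region.tsv",
            "summary": f"{config.out_prefix}.summary.tsv",
            "meta": f"{config.out_prefix}.meta.json",
        }
        _atomic_write(scan, paths["scan"])
        written.append(paths["scan"])
        _atomic_write(region_table, paths["region"])
        written.append(paths["region"])
        _atomic_write(summary, paths["summary"])
        written.append(paths["summary"])
        meta = {
            "package": "triadgxe",
            "version": __version__,
            "config": config.to_json_dict(),
            "n_families": cohort.n_families,
            "n_individuals": cohort.n_individuals,
            "n_snps": cohort.n_snps,
            "n_mendelian_violations": int(len(viol)),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(paths["meta"], "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
        written.append(paths["meta"])
        return {"paths": paths, "scan": scan, "regions": region_table,
                "summary": summary, "cohort": cohort, "meta": meta}
    except BaseException:
        for p in written:
            if os.path.exists(p):
                os.remove(p)
        raise


# ---------------------------------------------------------------------------
# flat key=value scenario files
# ---------------------------------------------------------------------------

_TUPLE_FIELDS = {"rm", "rc", "rcm", "rcf"}


def load_scenario(path: str) -> Scenario:
    """Parse a flat key=value scenario file.

    Pairs like ``rm = 1.0,1.5`` set (unexposed, exposed) relative risks;
    ``blocks = 10:0.8,5:0.0`` lists (n_snps, r) LD blocks.
    """
    kwargs = {}
    valid = {f.name for f in dataclasses.fields(Scenario)}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown scenario key {key!r}")
            if key == "blocks":
                kwargs[key] = tuple(
                    (int(p.split(":")[0]), float(p.split(":")[1]))
                    for p in val.split(","))
            elif key in _TUPLE_FIELDS:
                kwargs[key] = tuple(float(v) for v in val.split(","))
            elif key == "exposure":
                kwargs[key] = val
            elif key == "clp_only_effects":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif key in ("n_triads", "n_case_mother_dyads", "n_case_father_dyads",
                         "causal_snp"):
                kwargs[key] = int(val)
            else:
                kwargs[key] = float(val)
    return Scenario(**kwargs)
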