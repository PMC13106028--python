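"""End-to-end pipeline: simulate -> phenotype -> associate -> meta -> genes.

A single declarative config drives all stages; a run manifest records the
seed, per-stage row counts and input digests so a rerun with the same config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import VariantAssociationScan
from .cohorts import cohort_accounting
from .genetests import GeneBurdenScan, combine_studies
from .meta import FixedEffectsMeta
from .phenotype import PhenoParams, classify_ehr, classify_visits, clean_series
from .simulate import EHR_STYLE, SimConfig, simulate_cohort, write_cohort
from .tables import (read_covariates_tsv, read_weights_tsv,
                     write_phenotype_tsv)

log = logging.getLogger("copdwl")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full synthetic run."""

    sim: SimConfig = field(default_factory=SimConfig)
    sv_alpha: float = 5e-8
    gene_n_tests: int = 20000
    gene_alpha: float = 0.05
    mac_min_visit: float = 20
    mac_min_ehr: float = 40
    maf_max: float = 0.01
    pheno: PhenoParams = field(default_factory=PhenoParams)
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "phenotype", "assoc", "meta",
                               "gene", "gene-combine", "report")

    def __post_init__(self):
        if self.sv_alpha <= 0 or self.gene_alpha <= 0 or self.gene_n_tests <= 0:
            raise ValueError("thresholds must be positive")
        # one global seed expanded into per-stage substreams inside SimConfig
        self.sim.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        pheno = PhenoParams(**raw.pop("pheno", {}))
        return cls(sim=sim, pheno=pheno, **raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def _line_count(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


def phenotype_cohort(series: dict, covariates: pd.DataFrame, mode: str,
                     params: PhenoParams) -> tuple[list, dict]:
    """Clean and classify every participant of one cohort."""
    heights = covariates.set_index("participant_id").get("height_m")
    calls = []
    clean_counts = {"low_weight": 0, "low_bmi": 0, "iqr_outlier": 0}
    for pid in sorted(series):
        cleaned, report = clean_series(series[pid], params,
                                       apply_iqr=(mode == "ehr"))
        for k in clean_counts:
            clean_counts[k] += report.removed[k]
        h = float(heights.loc[pid]) if heights is not None and pid in heights.index else None
        if len(cleaned) == 0:
            from .phenotype import PhenotypeCall
            calls.append(PhenotypeCall(pid, "indeterminate", "none"))
            continue
        if mode == "ehr":
            calls.append(classify_ehr(cleaned, params, height_m=h))
        else:
            calls.append(classify_visits(cleaned, params, height_m=h))
    return calls, clean_counts


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run all configured stages in dependency order; return the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=logging.INFO, filename=outdir / "run.log", filemode="w",
        format="%(asctime)s %(levelname)s %(name)s %(message)s")
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "inputs": {}}
    stage = "simulate"
    try:
        cohorts = []
        study_assoc: dict[str, pd.DataFrame] = {}
        study_gene: dict[str, pd.DataFrame] = {}
        order = []
        for i in range(config.sim.n_cohorts):
            cohort = simulate_cohort(config.sim, i)
            cdir = outdir / cohort.name
            paths = write_cohort(cohort, cdir)
            manifest["inputs"][cohort.name] = {
                k: _digest(Path(p)) for k, p in paths.items()}
            cohorts.append(cohort)
            order.append(cohort.name)
        manifest["stages"]["simulate"] = {
            c.name: {"participants": c.genotypes.n_participants,
                     "variants": c.genotypes.n_variants} for c in cohorts}
        log.info("simulated %d cohorts", len(cohorts))

        stage = "phenotype"
        phenos: dict[str, pd.DataFrame] = {}
        for cohort in cohorts:
            mode = "ehr" if cohort.style == EHR_STYLE else "visits"
            calls, removed = phenotype_cohort(cohort.series, cohort.covariates,
                                              mode, config.pheno)
            ppath = outdir / cohort.name / "phenotype.tsv"
            write_phenotype_tsv(calls, ppath)
            pd.DataFrame([removed]).to_csv(
                outdir / cohort.name / "cleaning_report.tsv", sep="\t",
                index=False)
            phenos[cohort.name] = pd.DataFrame(
                {"participant_id": [c.participant_id for c in calls],
                 "status": [c.status for c in calls]})
            manifest["stages"].setdefault("phenotype", {})[cohort.name] = {
                "rows": len(calls), "cases": sum(c.is_case for c in calls),
                "removed": removed, "path_rows": _line_count(ppath) - 1}

        stage = "assoc"
        for cohort in cohorts:
            ph = phenos[cohort.name].set_index("participant_id")
            status = ph.loc[cohort.genotypes.participants, "status"]
            usable = status.isin(["case", "control"]).to_numpy()
            y = (status == "case").astype(int).to_numpy()[usable]
            idx = np.where(usable)[0]
            block = cohort.genotypes.subset_participants(idx)
            cov = cohort.covariates.set_index("participant_id").loc[
                block.participants].reset_index()
            mac_min = (config.mac_min_ehr if cohort.style == EHR_STYLE
                       else config.mac_min_visit)
            res = VariantAssociationScan(block, y, cov, mac_min=mac_min).fit()
            apath = res.to_tsv(outdir / cohort.name / "assoc.tsv")
            res.qq_manhattan(outdir / cohort.name, alpha=config.sv_alpha,
                             prefix="assoc")
            study_assoc[cohort.name] = res.summary()
            manifest["stages"].setdefault("assoc", {})[cohort.name] = {
                "rows": len(res.results),
                "nonconverged": res.n_nonconverged,
                "lambda": res.genomic_lambda() if len(res.results) else None,
                "path_rows": _line_count(apath) - 1}

        stage = "meta"
        meta = FixedEffectsMeta(study_assoc, study_order=order).fit()
        mpath = meta.to_tsv(outdir / "meta.tsv")
        hits = meta.significant_hits(config.sv_alpha)
        hits.to_csv(outdir / "meta_hits.tsv", sep="\t", index=False)
        manifest["stages"]["meta"] = {
            "rows": len(meta.results), "hits": len(hits),
            "path_rows": _line_count(mpath) - 1,
            "harmonize": asdict(meta.harmonize_report)
            if meta.harmonize_report else None}

        stage = "gene"
        for cohort in cohorts:
            ph = phenos[cohort.name].set_index("participant_id")
            status = ph.loc[cohort.genotypes.participants, "status"]
            usable = status.isin(["case", "control"]).to_numpy()
            y = (status == "case").astype(int).to_numpy()[usable]
            idx = np.where(usable)[0]
            block = cohort.genotypes.subset_participants(idx)
            cov = cohort.covariates.set_index("participant_id").loc[
                block.participants].reset_index()
            gres = GeneBurdenScan(block, cohort.masks, y, cov,
                                  maf_max=config.maf_max).fit()
            gpath = gres.to_tsv(outdir / cohort.name / "genes.tsv")
            study_gene[cohort.name] = gres.summary()
            manifest["stages"].setdefault("gene", {})[cohort.name] = {
                "rows": len(gres.results), "skipped": len(gres.skipped),
                "path_rows": _line_count(gpath) - 1}

        stage = "gene-combine"
        combined = combine_studies(study_gene, study_order=order)
        cpath = outdir / "genes_combined.tsv"
        combined.to_csv(cpath, sep="\t", index=False)
        threshold = config.gene_alpha / config.gene_n_tests
        manifest["stages"]["gene-combine"] = {
            "rows": len(combined), "threshold": threshold,
            "hits": int((combined["P_COMBINED"] < threshold).sum())
            if len(combined) else 0,
            "path_rows": _line_count(cpath) - 1}

        stage = "report"
        counts = pd.DataFrame(
            [{"cohort": c.name,
              "participants": c.genotypes.n_participants,
              "wl_count": int((phenos[c.name]["status"] == "case").sum())}
             for c in cohorts])
        report = cohort_accounting(counts)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        manifest["stages"]["report"] = report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
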