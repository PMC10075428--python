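"""Config-driven orchestration of the full analysis flow.

Stages run in a fixed order — QC, SNP association, gene-based test,
differential expression (or ingestion of an external DE table), evidence
combination, over-representation analysis, PRS — each writing its TSV
into the run directory, followed by a manifest recording the config
hash, seed, and library versions. Outputs are pure functions of
(inputs, config, seed): rerunning the same config and seed reproduces
every stage byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rarefuse import __version__
from rarefuse.io_formats import (
    read_counts, read_gene_regions, read_gmt, read_plink, read_vcf,
)
from rarefuse.qc import QCConfig, apply_qc, mds_components
from rarefuse.assoc_snp import assoc_table
from rarefuse.assoc_gene import gene_level_scan
from rarefuse.diffexpr import ingest_de_table, nb_wald_de
from rarefuse.integration import combined_gene_table
from rarefuse.enrichment import ora_test
from rarefuse.prs import compare_prs, compute_prs, select_prs_snps

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"  # fixed formatting keeps reruns byte-identical


@dataclass
class PipelineConfig:
    """One document pinning a full run."""

    seed: int
    output_dir: str
    plink_prefix: str | None = None
    vcf: str | None = None
    phenotype_table: str | None = None
    genes_bed: str | None = None
    gmt: str | None = None
    counts: str | None = None
    design: str | None = None
    de_table: str | None = None
    qc: dict = field(default_factory=dict)
    n_mds_covariates: int = 4
    genetest_window: int = 0
    genetest_sims: int = 1000
    genetest_max_sims: int = 100_000
    rescale_strategy: str = "minmax"
    alpha: float = 0.05
    prs_p_thresh: float = 0.05
    run_ora: bool = True
    run_prs: bool = True

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc)

    def validate(self) -> None:
        if self.plink_prefix is None and self.vcf is None:
            raise ValueError("config needs plink_prefix or vcf")
        if self.genes_bed is None:
            raise ValueError("config needs genes_bed")
        if self.de_table is None and (self.counts is None or self.design is None):
            raise ValueError("config needs counts+design or de_table")
        paths = [self.genes_bed, self.gmt, self.counts, self.design,
                 self.de_table, self.vcf, self.phenotype_table]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.plink_prefix is not None:
            for ext in (".bed", ".bim", ".fam"):
                if not Path(self.plink_prefix + ext).exists():
                    raise FileNotFoundError(self.plink_prefix + ext)

    def content_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("output_dir")  # hash pins the analysis, not its destination
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the in-memory stage results.

    Writes per-stage TSVs plus ``manifest.json`` into ``cfg.output_dir``.
    A stage failure aborts with the stage name; earlier outputs are left
    in place.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "load"
    try:
        if cfg.plink_prefix:
            ds = read_plink(cfg.plink_prefix)
        else:
            ds = read_vcf(cfg.vcf, phenotype_table=cfg.phenotype_table)
        genes = read_gene_regions(cfg.genes_bed)

        stage = "qc"
        ds, report = apply_qc(ds, QCConfig(**cfg.qc))
        _write(report.to_frame(), out / "qc_report.tsv")
        for step, ids in {**report.removed_snp_ids, **report.removed_sample_ids}.items():
            if ids:
                (out / f"qc_removed_{step}.txt").write_text("\n".join(ids) + "\n")
        results["qc_report"] = report
        results["genotypes"] = ds

        stage = "assoc"
        k = min(cfg.n_mds_covariates, max(ds.n_samples - 2, 1))
        covs = mds_components(ds, k) if cfg.n_mds_covariates > 0 else None
        snp_tab = assoc_table(ds, covs)
        _write(snp_tab, out / "snp_assoc.tsv")
        results["snp_assoc"] = snp_tab

        stage = "genetest"
        gene_tab = gene_level_scan(
            ds, snp_tab, genes, window=cfg.genetest_window,
            n_sims=cfg.genetest_sims, max_sims=cfg.genetest_max_sims,
            seed=cfg.seed,
        )
        _write(gene_tab, out / "gene_assoc.tsv")
        results["gene_assoc"] = gene_tab

        stage = "diffexpr"
        if cfg.de_table:
            de = ingest_de_table(cfg.de_table, alpha_bh=cfg.alpha)
        else:
            de = nb_wald_de(read_counts(cfg.counts, cfg.design), alpha_bh=cfg.alpha)
        _write(de, out / "de.tsv")
        results["de"] = de

        stage = "combine"
        combined = combined_gene_table(
            de, gene_tab, alpha=cfg.alpha, rescale_strategy=cfg.rescale_strategy,
        )
        _write(combined, out / "combined.tsv")
        results["combined"] = combined

        if cfg.run_ora and cfg.gmt:
            stage = "ora"
            universe = set(combined.loc[combined["in_both_datasets"], "gene_id"])
            hits = set(combined.loc[combined["significant"], "gene_id"])
            if hits:
                ora = ora_test(hits, read_gmt(cfg.gmt), universe)
            else:
                logger.warning("ora: no combined-significant genes; empty table")
                ora = pd.DataFrame(columns=[
                    "set_name", "set_size_in_universe", "hits_in_set",
                    "hits_total", "universe_size", "p_hyper", "overlap_genes",
                    "p_bh",
                ])
            _write(ora, out / "ora.tsv")
            results["ora"] = ora

        if cfg.run_prs:
            stage = "prs"
            weights = select_prs_snps(snp_tab, combined, genes, cfg.prs_p_thresh)
            _write(weights, out / "prs_weights.tsv")
            results["prs_weights"] = weights
            if len(weights):
                scores = compute_prs(ds, weights)
                _write(scores, out / "prs_scores.tsv")
                results["prs_scores"] = scores
                comparison = compare_prs(scores)
                _write(pd.DataFrame([comparison]), out / "prs_comparison.tsv")
                results["prs_comparison"] = comparison

        stage = "manifest"
        manifest = {
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "versions": {
                "rarefuse": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": sorted(p.name for p in out.iterdir() if p.suffix in (".tsv", ".txt")),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        results["manifest"] = manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def write_simulated_inputs(spec, outdir: str) -> dict:
    """Materialize a simulated study as on-disk pipeline inputs.

    Writes PLINK bed/bim/fam + VCF + phenotype TSV, gene BED, GMT, counts
    and design TSVs, and the ground truth JSON; returns a ready
    PipelineConfig kwargs dict (minus seed/output_dir).
    """
    from rarefuse.io_formats import (
        write_counts, write_gene_regions, write_gmt, write_plink, write_vcf,
    )
    from rarefuse.synthetic_data import simulate_study

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(spec)
    ds = study["genotypes"]
    write_plink(ds, str(out / "cohort"))
    write_vcf(ds, str(out / "cohort.vcf"))
    pheno = pd.DataFrame({
        "sample": ds.sample_ids,
        "phenotype": np.where(ds.phenotype == 1, "case",
                              np.where(ds.phenotype == 0, "control", "missing")),
        "sex": np.where(ds.sex == 1, "male", np.where(ds.sex == 2, "female", "unknown")),
    })
    pheno.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    write_gene_regions(study["genes"], str(out / "genes.bed"))
    write_gmt(study["gene_sets"], str(out / "sets.gmt"))
    write_counts(study["counts"], str(out / "counts.tsv"), str(out / "design.tsv"))
    study["truth"].to_json(str(out / "ground_truth.json"))
    return {
        "plink_prefix": str(out / "cohort"),
        "phenotype_table": str(out / "phenotype.tsv"),
        "genes_bed": str(out / "genes.bed"),
        "gmt": str(out / "sets.gmt"),
        "counts": str(out / "counts.tsv"),
        "design": str(out / "design.tsv"),
    }
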