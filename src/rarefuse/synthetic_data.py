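"""Seeded generators for every input the pipeline consumes.

The generators emulate the study design the pipeline targets: a small
case/control cohort with a rare binary outcome genotyped at LD-blocked
biallelic SNPs of common frequency, a UTR-inclusive gene annotation
tiling the SNPs, gene sets, and a small paired pre/post-treatment
expression experiment on a handful of cell lines. Causal SNPs are
concentrated in a subset of genes; differentially expressed genes include
those causal genes (the assumption the evidence fusion relies on) plus
extras. Every planted signal is recorded in a :class:`GroundTruth` so
recovery can be scored exactly.

LD is produced by thresholding AR(1) latent Gaussian haplotypes — enough
correlation structure to exercise LD-aware tests, with none of the
demographic realism of a coalescent simulator. Everything is
deterministic per seed.

Two stock configurations are provided: :func:`demo_spec` mirrors the
rare-disease scale this pipeline is meant for (87 samples, ~12 cases, six
cell-line pairs), exercising the small-sample code paths;
:func:`powered_spec` is larger (600 samples, 20% cases) so statistical
recovery claims can actually be measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from rarefuse.io_formats import (
    CASE, CONTROL, FEMALE, MALE,
    CountsMatrix, GeneRegion, GeneSetCollection, GenotypeDataset,
)

_SNP_SPACING = 1_000  # bp between adjacent simulated SNPs
_GENE_MARGIN = 200  # bp of "UTR" padding around a gene's SNPs


@dataclass
class SimSpec:
    """Parameters of the synthetic study; defaults mirror the target scale."""

    n_samples: int = 87
    prevalence: float = 12 / 87
    n_genes: int = 100
    snps_per_gene: int = 15
    n_x_snps: int = 40
    ld_rho: float = 0.6  # AR(1) latent correlation between adjacent SNPs
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    # association signal
    n_causal_genes: int = 6
    causal_snps_per_gene: int = 2
    causal_beta: float = 1.2  # per-allele log odds
    # expression signal
    n_de_extra_genes: int = 6  # DE genes beyond the causal ones
    de_log2fc: float = 1.5
    nb_dispersion: float = 0.05
    n_cell_lines: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.n_causal_genes > self.n_genes:
            raise ValueError("causal genes must be a subset of the gene list")
        if self.causal_snps_per_gene > self.snps_per_gene:
            raise ValueError("more causal SNPs than SNPs per gene")
        if not np.isfinite(self.causal_beta):
            raise ValueError("effects must be finite")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


def demo_spec(seed: int = 0) -> SimSpec:
    """Rare-disease-scale configuration (87 samples, ~14% cases)."""
    return SimSpec(seed=seed)


def powered_spec(seed: int = 0) -> SimSpec:
    """Well-powered configuration for measuring statistical recovery."""
    return SimSpec(
        n_samples=800, prevalence=0.25, n_genes=300, snps_per_gene=5,
        n_causal_genes=15, causal_snps_per_gene=2, causal_beta=0.8,
        n_de_extra_genes=10, de_log2fc=1.5, nb_dispersion=0.05,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Everything that was planted, for exact recovery scoring."""

    causal_snps: dict[str, float] = field(default_factory=dict)  # id -> beta
    causal_genes: list[str] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)  # id -> log2FC
    violations: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _stage_rng(spec: SimSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(8)[stage])


def _sim_haplotypes(
    rng: np.random.Generator, n_hap: int, mafs: np.ndarray, rho: float
) -> np.ndarray:
    """AR(1) latent Gaussians thresholded at each SNP's MAF quantile."""
    L = mafs.size
    z = np.empty((n_hap, L))
    z[:, 0] = rng.standard_normal(n_hap)
    innov = rng.standard_normal((n_hap, L))
    c = np.sqrt(1.0 - rho**2)
    for j in range(1, L):
        z[:, j] = rho * z[:, j - 1] + c * innov[:, j]
    thresh = stats.norm.ppf(mafs)
    return (z < thresh).astype(np.int8)


def sim_genotypes(spec: SimSpec):
    """Simulate genotypes, gene regions, and the (association) ground truth.

    Returns (GenotypeDataset, genes, GroundTruth). The dataset has one
    AR(1) LD block per gene on autosomes 1..22, an X chromosome block
    (males hemizygous, coded homozygous), assigned sex, and a still-missing
    phenotype (see :func:`sim_phenotype`). Gene regions tile the autosomal
    SNPs with a UTR-like margin.
    """
    rng = _stage_rng(spec, 0)
    n = spec.n_samples
    lo, hi = spec.maf_range

    variants = []
    dosage_blocks = []
    genes: list[GeneRegion] = []
    pos_cursor = {}
    for g in range(spec.n_genes):
        chrom = str(g % 22 + 1)
        start_pos = pos_cursor.get(chrom, 0) + 10 * _SNP_SPACING
        mafs = rng.uniform(lo, hi, size=spec.snps_per_gene)
        hap1 = _sim_haplotypes(rng, n, mafs, spec.ld_rho)
        hap2 = _sim_haplotypes(rng, n, mafs, spec.ld_rho)
        dosage_blocks.append(hap1 + hap2)
        positions = start_pos + np.arange(spec.snps_per_gene) * _SNP_SPACING
        for j, p in enumerate(positions):
            variants.append((f"rs_g{g}_{j}", chrom, int(p), "A", "G"))
        genes.append(GeneRegion(
            f"GENE{g:04d}", chrom,
            int(positions[0] - _GENE_MARGIN), int(positions[-1] + _GENE_MARGIN),
        ))
        pos_cursor[chrom] = int(positions[-1])

    sex = np.where(rng.random(n) < 0.5, MALE, FEMALE).astype(np.int8)
    if spec.n_x_snps:
        x_mafs = rng.uniform(lo, hi, size=spec.n_x_snps)
        hap1 = _sim_haplotypes(rng, n, x_mafs, spec.ld_rho)
        hap2 = _sim_haplotypes(rng, n, x_mafs, spec.ld_rho)
        x_dos = hap1 + hap2
        male = sex == MALE
        x_dos[male] = 2 * hap1[male]  # hemizygous, coded homozygous
        dosage_blocks.append(x_dos.astype(np.int8))
        for j in range(spec.n_x_snps):
            variants.append((f"rs_x_{j}", "X", (j + 1) * _SNP_SPACING, "A", "G"))

    dosage = np.concatenate(dosage_blocks, axis=1).astype(np.int8)
    if spec.missing_rate > 0:
        miss = rng.random(dosage.shape) < spec.missing_rate
        dosage[miss] = -1

    variants_df = pd.DataFrame(
        variants,
        columns=["id", "chromosome", "position", "counted_allele", "other_allele"],
    )
    ds = GenotypeDataset(
        sample_ids=[f"S{i:04d}" for i in range(n)],
        phenotype=np.full(n, -9, dtype=np.int8),
        sex=sex,
        variants=variants_df,
        dosage=dosage,
    )

    truth = GroundTruth()
    causal_gene_idx = rng.choice(spec.n_genes, size=spec.n_causal_genes, replace=False)
    for g in sorted(causal_gene_idx):
        truth.causal_genes.append(f"GENE{g:04d}")
        snp_idx = rng.choice(
            spec.snps_per_gene, size=spec.causal_snps_per_gene, replace=False
        )
        for j in sorted(snp_idx):
            truth.causal_snps[f"rs_g{g}_{j}"] = spec.causal_beta

    de_pool = [f"GENE{g:04d}" for g in range(spec.n_genes)
               if f"GENE{g:04d}" not in truth.causal_genes]
    extra = rng.choice(len(de_pool), size=spec.n_de_extra_genes, replace=False)
    for gid in truth.causal_genes:
        truth.de_genes[gid] = spec.de_log2fc
    for i in sorted(extra):
        truth.de_genes[de_pool[i]] = spec.de_log2fc
    return ds, genes, truth


def sim_phenotype(
    ds: GenotypeDataset, truth: GroundTruth, spec: SimSpec
) -> GenotypeDataset:
    """Draw a binary phenotype from a logistic model on the causal SNPs.

    The intercept is solved numerically so the expected case fraction
    matches the target prevalence. Returns a copy of ``ds`` with
    phenotype filled in.
    """
    rng = _stage_rng(spec, 1)
    idx = pd.Index(ds.variants["id"])
    cols = idx.get_indexer(list(truth.causal_snps))
    if (cols < 0).any():
        raise ValueError("causal SNPs not present in dataset")
    x = ds.dosage_float()[:, cols]
    x = np.where(np.isnan(x), np.nanmean(x, axis=0), x)
    betas = np.array(list(truth.causal_snps.values()))
    eta = x @ betas

    def mean_prev(b0):
        return np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))) - spec.prevalence

    try:
        b0 = optimize.brentq(mean_prev, -40, 40)
    except ValueError as exc:
        raise ValueError(f"prevalence {spec.prevalence} unattainable") from exc
    prob = 1.0 / (1.0 + np.exp(-(b0 + eta)))
    pheno = np.where(rng.random(ds.n_samples) < prob, CASE, CONTROL).astype(np.int8)

    out = ds.subset()
    out.phenotype = pheno
    return out


def sim_counts(spec: SimSpec, truth: GroundTruth) -> CountsMatrix:
    """Paired pre/post NB counts for all genes, with planted log2FCs.

    Per-gene baseline log-means, per-line random baselines, per-sample
    library-size factors, and a condition effect of ``de_log2fc`` (log2)
    on the planted DE genes; NB noise at ``nb_dispersion``.
    """
    if spec.n_cell_lines < 3:
        raise ValueError("need >= 3 cell lines for a paired design")
    if spec.nb_dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = _stage_rng(spec, 2)
    gene_ids = [f"GENE{g:04d}" for g in range(spec.n_genes)]
    n_s = 2 * spec.n_cell_lines
    lines = [f"LCL{i}" for i in range(spec.n_cell_lines)]
    sample_ids = [f"{l}_{c}" for l in lines for c in ("pre", "post")]
    condition = np.array([c for _ in lines for c in ("pre", "post")], dtype=object)
    pairing = np.array([l for l in lines for _ in ("pre", "post")], dtype=object)

    base_log = rng.uniform(np.log(20), np.log(500), size=spec.n_genes)
    line_effect = rng.normal(0.0, 0.10, size=(spec.n_genes, spec.n_cell_lines))
    lib = np.exp(rng.normal(0.0, 0.15, size=n_s))
    lfc_ln = np.array([
        truth.de_genes.get(g, 0.0) * np.log(2.0) for g in gene_ids
    ])

    log_mu = np.empty((spec.n_genes, n_s))
    for s in range(n_s):
        line_ix = s // 2
        is_post = condition[s] == "post"
        log_mu[:, s] = (
            base_log + line_effect[:, line_ix]
            + (lfc_ln if is_post else 0.0) + np.log(lib[s])
        )
    mu = np.exp(log_mu)
    if spec.nb_dispersion > 0:
        r = 1.0 / spec.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    return CountsMatrix(gene_ids, sample_ids, condition, pairing,
                        counts.astype(np.int64))


# ---------------------------------------------------------------------------
# planted QC violations
# ---------------------------------------------------------------------------

@dataclass
class ViolationSpec:
    """How many of each QC violation to plant."""

    n_high_missing_snps: int = 0
    n_sex_mismatches: int = 0
    n_low_maf_snps: int = 0
    n_hwe_snps: int = 0
    n_duplicate_pairs: int = 0
    n_het_outliers: int = 0
    n_ancestry_outliers: int = 0
    seed: int = 0


def plant_violations(
    ds: GenotypeDataset, vspec: ViolationSpec, truth: GroundTruth | None = None
) -> tuple[GenotypeDataset, GroundTruth]:
    """Inject QC violations at controlled, disjoint positions.

    SNP violations land on distinct autosomal SNPs; sample violations on
    distinct samples (duplicate pairs use two samples each). The exact
    planted lists are recorded in the returned GroundTruth. Raises if the
    requested counts cannot be allocated disjointly.
    """
    rng = np.random.default_rng(vspec.seed)
    ds = ds.subset()  # work on a copy
    truth = truth or GroundTruth()
    n, m = ds.n_samples, ds.n_variants
    auto = np.where(~ds.variants["chromosome"].isin(["X", "x", "23"]).values)[0]

    n_snp_viol = vspec.n_high_missing_snps + vspec.n_low_maf_snps + vspec.n_hwe_snps
    if n_snp_viol > auto.size:
        raise ValueError("not enough autosomal SNPs for the requested violations")
    n_sample_viol = (vspec.n_sex_mismatches + 2 * vspec.n_duplicate_pairs
                     + vspec.n_het_outliers + vspec.n_ancestry_outliers)
    if n_sample_viol > n:
        raise ValueError("not enough samples for the requested violations")

    snp_pool = list(rng.choice(auto, size=n_snp_viol, replace=False))
    sample_pool = list(rng.choice(n, size=n_sample_viol, replace=False))

    def take_snps(k):
        return [snp_pool.pop() for _ in range(k)]

    def take_samples(k):
        return [sample_pool.pop() for _ in range(k)]

    viol = truth.violations

    cols = take_snps(vspec.n_high_missing_snps)
    for j in cols:
        rows = rng.choice(n, size=max(1, n // 2), replace=False)
        ds.dosage[rows, j] = -1
    viol["high_missing_snps"] = list(ds.variants.loc[cols, "id"])

    idx = take_samples(vspec.n_sex_mismatches)
    for i in idx:
        ds.sex[i] = MALE if ds.sex[i] == FEMALE else FEMALE
    viol["sex_mismatches"] = [ds.sample_ids[i] for i in idx]

    cols = take_snps(vspec.n_low_maf_snps)
    n_carriers = max(1, int(round(0.02 * n)))  # MAF ~ 0.01, safely < 0.05
    for j in cols:
        ds.dosage[:, j] = 0
        carriers = rng.choice(n, size=n_carriers, replace=False)
        ds.dosage[carriers, j] = 1
    viol["low_maf_snps"] = list(ds.variants.loc[cols, "id"])

    cols = take_snps(vspec.n_hwe_snps)
    for j in cols:
        ds.dosage[:, j] = 1  # universal heterozygosity: extreme HWE violation
    viol["hwe_snps"] = list(ds.variants.loc[cols, "id"])

    dup_removed = []
    for _ in range(vspec.n_duplicate_pairs):
        a, b = take_samples(2)
        ds.dosage[b] = ds.dosage[a]
        ds.sex[b] = ds.sex[a]
        # extra missingness marks b as the member to drop
        miss = rng.choice(m, size=max(1, m // 50), replace=False)
        ds.dosage[b, miss] = -1
        dup_removed.append(ds.sample_ids[b])
    viol["duplicate_samples"] = dup_removed

    idx = take_samples(vspec.n_het_outliers)
    for i in idx:
        ds.dosage[i, auto] = 1
    viol["het_outliers"] = [ds.sample_ids[i] for i in idx]

    idx = take_samples(vspec.n_ancestry_outliers)
    if idx:
        # avoid SNPs carrying other planted violations: redrawing their
        # genotypes would change which QC step catches them
        violated = set()
        for key in ("high_missing_snps", "low_maf_snps", "hwe_snps"):
            violated |= set(viol.get(key, []))
        clean_auto = np.array([
            j for j in auto if ds.variants.loc[j, "id"] not in violated
        ])
        flip_cols = clean_auto[rng.random(clean_auto.size) < 0.5]
        freq = np.clip(np.nanmean(
            np.where(ds.dosage[:, flip_cols] == -1, np.nan,
                     ds.dosage[:, flip_cols].astype(float)), axis=0) / 2.0,
            0.02, 0.98)
        for i in idx:
            ds.dosage[i, flip_cols] = rng.binomial(2, 1.0 - freq).astype(np.int8)
    viol["ancestry_outliers"] = [ds.sample_ids[i] for i in idx]

    return ds, truth


def sim_gene_sets(
    spec: SimSpec, truth: GroundTruth, n_sets: int = 20, set_size: int = 15
) -> GeneSetCollection:
    """Random gene sets plus one set enriched in the causal genes."""
    rng = _stage_rng(spec, 3)
    gene_ids = [f"GENE{g:04d}" for g in range(spec.n_genes)]
    sets, desc = {}, {}
    for k in range(n_sets):
        members = rng.choice(gene_ids, size=min(set_size, spec.n_genes), replace=False)
        sets[f"SET{k:02d}"] = set(members)
        desc[f"SET{k:02d}"] = "random synthetic set"
    enriched = set(truth.causal_genes)
    filler = [g for g in gene_ids if g not in enriched]
    pad = rng.choice(len(filler), size=min(5, len(filler)), replace=False)
    enriched |= {filler[i] for i in pad}
    sets["CAUSAL_SET"] = enriched
    desc["CAUSAL_SET"] = "synthetic set enriched in planted causal genes"
    return GeneSetCollection(sets=sets, descriptions=desc)


def simulate_study(spec: SimSpec):
    """One call producing every pipeline input plus the ground truth.

    Returns a dict with keys: genotypes (phenotype assigned), genes,
    counts, gene_sets, truth.
    """
    ds, genes, truth = sim_genotypes(spec)
    ds = sim_phenotype(ds, truth, spec)
    counts = sim_counts(spec, truth)
    gene_sets = sim_gene_sets(spec, truth)
    return {
        "genotypes": ds, "genes": genes, "counts": counts,
        "gene_sets": gene_sets, "truth": truth,
    }
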