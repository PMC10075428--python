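"""Genotype quality-control cascade for a case/control exome cohort.

The cascade mirrors the classic PLINK-era workflow, applied in a fixed
order: SNP missingness, sample missingness, sex-check mismatches, minor
allele frequency, Hardy-Weinberg equilibrium, heterozygosity outliers,
cryptic relatedness, and ancestry (stratification) outliers on MDS
components. MAF and HWE are recomputed on the sample set current at their
step, so the totals depend on the order — which is why the order is fixed
and every step's removals are reported.

Non-autosomal variants are dropped immediately after the sex check (they
are needed for it, but hemizygous male X genotypes would corrupt the
downstream autosomal MAF/HWE/heterozygosity statistics); the drop is
recorded in the report so the conservation invariant still reconciles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from rarefuse.io_formats import FEMALE, MALE, GenotypeDataset

logger = logging.getLogger(__name__)

_NON_AUTOSOMES = {"X", "x", "23", "Y", "y", "24", "XY", "25", "MT", "M", "26"}


@dataclass
class QCConfig:
    """Thresholds for the QC cascade; defaults are field-standard."""

    max_snp_missing: float = 0.20
    max_sample_missing: float = 0.20
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    het_sd_mult: float = 3.0
    relatedness_threshold: float = 0.185  # PI_HAT
    mds_components: int = 10
    ancestry_sd_mult: float = 3.0

    def __post_init__(self):
        for name in ("max_snp_missing", "max_sample_missing", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("het_sd_mult", "ancestry_sd_mult"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class QCReport:
    """Ordered per-step removal counts; conservation must reconcile."""

    initial_snps: int = 0
    initial_samples: int = 0
    snp_steps: dict[str, int] = field(default_factory=dict)
    sample_steps: dict[str, int] = field(default_factory=dict)
    removed_snp_ids: dict[str, list[str]] = field(default_factory=dict)
    removed_sample_ids: dict[str, list[str]] = field(default_factory=dict)
    final_snps: int = 0
    final_samples: int = 0

    def validate(self) -> None:
        if self.initial_snps - sum(self.snp_steps.values()) != self.final_snps:
            raise AssertionError("QCReport SNP counts do not reconcile")
        if self.initial_samples - sum(self.sample_steps.values()) != self.final_samples:
            raise AssertionError("QCReport sample counts do not reconcile")

    def to_frame(self):
        import pandas as pd

        rows = [("initial", "snp", self.initial_snps),
                ("initial", "sample", self.initial_samples)]
        rows += [(k, "snp", v) for k, v in self.snp_steps.items()]
        rows += [(k, "sample", v) for k, v in self.sample_steps.items()]
        rows += [("final", "snp", self.final_snps),
                 ("final", "sample", self.final_samples)]
        return pd.DataFrame(rows, columns=["step", "axis", "count"])


# ---------------------------------------------------------------------------
# per-step operations
# ---------------------------------------------------------------------------

def snp_missingness_filter(
    ds: GenotypeDataset, max_rate: float
) -> tuple[GenotypeDataset, list[str]]:
    """Drop SNPs whose missing-genotype fraction strictly exceeds ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0,1]")
    rate = (ds.dosage == -1).mean(axis=0) if ds.n_samples else np.zeros(ds.n_variants)
    keep = rate <= max_rate
    removed = list(ds.variants.loc[~keep, "id"])
    return ds.subset(variant_idx=np.where(keep)[0]), removed


def sample_missingness_filter(
    ds: GenotypeDataset, max_rate: float
) -> tuple[GenotypeDataset, list[str]]:
    """Drop samples whose missing fraction strictly exceeds ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0,1]")
    rate = (ds.dosage == -1).mean(axis=1) if ds.n_variants else np.zeros(ds.n_samples)
    keep = rate <= max_rate
    removed = [s for s, k in zip(ds.sample_ids, keep) if not k]
    return ds.subset(sample_idx=np.where(keep)[0]), removed


def sex_check(ds: GenotypeDataset):
    """X-heterozygosity inbreeding F per sample, with mismatch flags.

    F = (obs_hom - exp_hom) / (n - exp_hom) over non-missing X SNPs,
    exp_hom summing per-SNP 1 - 2p(1-p). A recorded female with F > 0.8 or
    a recorded male with F < 0.2 is flagged as a mismatch; samples with no
    usable X genotypes are flagged "undetermined". Returns
    (F array, mismatch sample ids, undetermined sample ids); all empty
    with a logged notice when the dataset has no X SNPs.
    """
    on_x = ds.variants["chromosome"].isin(["X", "x", "23"]).values
    if not on_x.any():
        logger.info("sex_check: no X-chromosome SNPs; step skipped")
        return np.full(ds.n_samples, np.nan), [], []
    x = ds.dosage[:, on_x].astype(np.float64)
    miss = x == -1
    x[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0) / 2.0
    exp_hom_per_snp = 1.0 - 2.0 * p * (1.0 - p)

    nonmiss = ~miss
    n_obs = nonmiss.sum(axis=1).astype(float)
    obs_hom = ((x == 0) | (x == 2)).sum(axis=1).astype(float)
    exp_hom = nonmiss @ exp_hom_per_snp

    F = np.full(ds.n_samples, np.nan)
    denom = n_obs - exp_hom
    ok = (n_obs > 0) & (np.abs(denom) > 1e-12)
    F[ok] = (obs_hom[ok] - exp_hom[ok]) / denom[ok]

    mismatched, undetermined = [], []
    for i, sid in enumerate(ds.sample_ids):
        if n_obs[i] == 0 or not np.isfinite(F[i]):
            undetermined.append(sid)
        elif ds.sex[i] == FEMALE and F[i] > 0.8:
            mismatched.append(sid)
        elif ds.sex[i] == MALE and F[i] < 0.2:
            mismatched.append(sid)
    return F, mismatched, undetermined


def counted_allele_freq(ds: GenotypeDataset) -> np.ndarray:
    """Per-variant frequency of the counted allele over non-missing genotypes."""
    x = ds.dosage_float()
    with np.errstate(invalid="ignore"):
        return np.nanmean(x, axis=0) / 2.0


def orient_minor(ds: GenotypeDataset) -> GenotypeDataset:
    """Return a copy oriented so the counted allele is the minor allele.

    SNPs whose counted-allele frequency strictly exceeds 0.5 have dosage
    flipped (x -> 2 - x) and allele labels swapped; ties (frequency
    exactly 0.5) keep the original orientation.
    """
    out = ds.subset()
    freq = counted_allele_freq(out)
    flip = freq > 0.5
    if flip.any():
        cols = np.where(flip)[0]
        block = out.dosage[:, cols]
        out.dosage[:, cols] = np.where(
            block == -1, np.int8(-1), (2 - block).astype(np.int8))
        a1 = out.variants.loc[cols, "counted_allele"].copy()
        out.variants.loc[cols, "counted_allele"] = out.variants.loc[cols, "other_allele"].values
        out.variants.loc[cols, "other_allele"] = a1.values
    return out


def maf_filter(
    ds: GenotypeDataset, min_maf: float, orient: bool = True
) -> tuple[GenotypeDataset, list[str]]:
    """Drop SNPs with MAF < ``min_maf``; optionally orient to the minor allele.

    MAF is computed on non-missing genotypes. With ``orient`` (default)
    the retained SNPs are re-oriented via :func:`orient_minor`. Inside the
    full cascade the orientation instead happens once at the end, after
    all sample removals, so the choice of counted allele is stable.
    """
    freq = counted_allele_freq(ds)
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)  # all-missing counts as monomorphic
    keep = maf >= min_maf
    removed = list(ds.variants.loc[~keep, "id"])
    out = ds.subset(variant_idx=np.where(keep)[0])
    if orient:
        out = orient_minor(out)
    return out, removed


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    all heterozygote counts no more probable than the observed one
    (standard exact test, not mid-p). Uses the numerically stable
    mode-anchored recurrence over heterozygote counts.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one genotype required")
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)  # rarer allele count
    if rare == 0:
        return 1.0

    # heterozygote counts share the parity of the rare-allele count
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1

    n_het_max = rare if rare % 2 == mid % 2 else rare - 1
    probs = {mid: 1.0}
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 * nAA(h-2+2)/... )
    h = mid
    while h >= 2:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        nxt = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
        probs[h - 2] = nxt
        h -= 2
    h = mid
    while h + 2 <= rare:
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        nxt = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        probs[h + 2] = nxt
        h += 2

    total = sum(probs.values())
    obs = probs[n_Aa] / total
    p = sum(v for v in probs.values() if v / total <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_filter(
    ds: GenotypeDataset, alpha: float
) -> tuple[GenotypeDataset, list[str], np.ndarray]:
    """Drop SNPs whose exact HWE p-value is below ``alpha``."""
    pvals = np.ones(ds.n_variants)
    for j in range(ds.n_variants):
        col = ds.dosage[:, j]
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        if n_aa + n_het + n_AA > 0:
            pvals[j] = hwe_exact(n_AA, n_het, n_aa)
    keep = pvals >= alpha
    removed = list(ds.variants.loc[~keep, "id"])
    return ds.subset(variant_idx=np.where(keep)[0]), removed, pvals


def het_outlier_filter(ds: GenotypeDataset, sd_mult: float) -> list[str]:
    """Flag samples whose autosomal heterozygosity rate is > sd_mult SDs
    from the cohort mean. Requires >= 3 samples; SD of zero flags nobody."""
    if ds.n_samples < 3:
        raise ValueError("heterozygosity outlier detection needs >= 3 samples")
    autosomal = ~ds.variants["chromosome"].isin(_NON_AUTOSOMES).values
    x = ds.dosage[:, autosomal]
    nonmiss = (x != -1).sum(axis=1).astype(float)
    het = (x == 1).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(nonmiss > 0, het / nonmiss, np.nan)
    mean, sd = np.nanmean(rate), np.nanstd(rate, ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        return []
    out = np.isfinite(rate) & (np.abs(rate - mean) > sd_mult * sd)
    return [ds.sample_ids[i] for i in np.where(out)[0]]


def _ibs_state_counts(ds: GenotypeDataset):
    """Pairwise IBS-state counts and per-pair expectation sums, via matmuls.

    Returns (ibs0, ibs1, ibs2, nn, e) where each is an n x n matrix; ``e``
    is a dict of summed per-SNP conditional IBS expectations over the SNPs
    non-missing in both members of each pair.
    """
    d = ds.dosage
    G0 = (d == 0).astype(np.float64)
    G1 = (d == 1).astype(np.float64)
    G2 = (d == 2).astype(np.float64)
    M = (d != -1).astype(np.float64)

    ibs2 = G0 @ G0.T + G1 @ G1.T + G2 @ G2.T
    ibs0 = G0 @ G2.T + G2 @ G0.T
    nn = M @ M.T
    ibs1 = nn - ibs2 - ibs0

    p = counted_allele_freq(ds)
    p = np.clip(np.nan_to_num(p, nan=0.5), 1e-6, 1 - 1e-6)
    q = 1.0 - p
    e = {
        "ibs0_ibd0": 2.0 * p**2 * q**2,
        "ibs1_ibd0": 4.0 * p**3 * q + 4.0 * p * q**3,
        "ibs2_ibd0": p**4 + q**4 + 4.0 * p**2 * q**2,
        "ibs1_ibd1": 2.0 * p**2 * q + 2.0 * p * q**2,
        "ibs2_ibd1": p**3 + q**3 + p**2 * q + p * q**2,
    }
    esums = {k: M @ (M * v).T for k, v in ((k, e[k]) for k in e)}
    return ibs0, ibs1, ibs2, nn, esums


def relatedness(
    ds: GenotypeDataset, threshold: float = 0.185
):
    """Method-of-moments IBD (PLINK --genome style) from IBS-state counts.

    Returns (pihat_matrix, flagged_pairs, samples_to_remove). For each
    flagged pair the member with the higher missingness rate is marked for
    removal (first member on ties), and a sample is listed at most once.
    """
    if ds.n_samples < 2:
        raise ValueError("relatedness needs >= 2 samples")
    ibs0, ibs1, ibs2, nn, e = _ibs_state_counts(ds)
    with np.errstate(invalid="ignore", divide="ignore"):
        # expectation sums are per-pair counts, so p0/p1 are probabilities
        p0 = ibs0 / e["ibs0_ibd0"]
        p1 = (ibs1 - p0 * e["ibs1_ibd0"]) / e["ibs1_ibd1"]
        p2 = (ibs2 - p0 * e["ibs2_ibd0"] - p1 * e["ibs2_ibd1"]) / nn
    p0 = np.clip(np.nan_to_num(p0), 0.0, 1.0)
    p1 = np.clip(np.nan_to_num(p1), 0.0, 1.0)
    p2 = np.clip(np.nan_to_num(p2), 0.0, 1.0)
    tot = p0 + p1 + p2
    scale = np.where(tot > 1.0, tot, 1.0)
    p1, p2 = p1 / scale, p2 / scale
    pihat = np.clip(p1 / 2.0 + p2, 0.0, 1.0)
    np.fill_diagonal(pihat, 1.0)

    miss_rate = (ds.dosage == -1).mean(axis=1)
    flagged, to_remove = [], []
    iu = np.triu_indices(ds.n_samples, k=1)
    for i, j in zip(*iu):
        if pihat[i, j] > threshold:
            flagged.append((ds.sample_ids[i], ds.sample_ids[j], float(pihat[i, j])))
            worse = i if miss_rate[i] >= miss_rate[j] else j
            sid = ds.sample_ids[worse]
            if sid not in to_remove:
                to_remove.append(sid)
    return pihat, flagged, to_remove


def ibs_distance(ds: GenotypeDataset) -> np.ndarray:
    """Pairwise distance 1 - mean IBS similarity, pairwise-complete."""
    ibs0, ibs1, ibs2, nn, _ = _ibs_state_counts(ds)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = (ibs2 + 0.5 * ibs1) / nn
    sim = np.nan_to_num(sim, nan=0.0)
    d = 1.0 - sim
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


def mds_components(ds: GenotypeDataset, k: int) -> np.ndarray:
    """Classical MDS (principal coordinates) on 1 - IBS similarity.

    Components are ordered by eigenvalue; if fewer than ``k`` positive
    eigenvalues exist the remaining columns are zero-padded with a warning.
    """
    if k >= ds.n_samples:
        raise ValueError("k must be smaller than the sample count")
    d = ibs_distance(ds)
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    n_pos = int(pos.sum())
    comps = np.zeros((n, k))
    use = min(k, n_pos)
    comps[:, :use] = vecs[:, :use] * np.sqrt(vals[:use])
    if use < k:
        logger.warning(
            "mds_components: only %d positive eigenvalues; padding to k=%d with zeros",
            n_pos, k,
        )
    return comps


def ancestry_outlier_filter(components: np.ndarray, sd_mult: float) -> list[int]:
    """Flag samples (by row index) far from the centroid of the first two
    MDS components: distance more than sd_mult SDs above the mean distance.

    Centroid distances are non-negative with a Rayleigh-like null shape,
    so the cutoff is offset by the mean — a bare multiple of the SD would
    flag a sizeable share of a perfectly homogeneous cohort."""
    if components.shape[1] < 2:
        raise ValueError("need >= 2 components")
    xy = components[:, :2]
    centroid = xy.mean(axis=0)
    dist = np.sqrt(((xy - centroid) ** 2).sum(axis=1))
    sd = dist.std(ddof=1) if len(dist) > 1 else 0.0
    if sd == 0.0:
        return []
    return list(np.where(dist > dist.mean() + sd_mult * sd)[0])


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def apply_qc(
    ds: GenotypeDataset, cfg: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Run the full ordered QC cascade and return the filtered dataset plus
    a per-step removal report.

    Steps: SNP missingness -> sample missingness -> sex mismatches ->
    (non-autosomal drop) -> MAF -> HWE -> heterozygosity outliers ->
    relatedness -> ancestry outliers. MAF and HWE are recomputed on the
    samples surviving the earlier steps.
    """
    cfg = cfg or QCConfig()
    rep = QCReport(initial_snps=ds.n_variants, initial_samples=ds.n_samples)

    ds, rem = snp_missingness_filter(ds, cfg.max_snp_missing)
    rep.snp_steps["snp_missingness"] = len(rem)
    rep.removed_snp_ids["snp_missingness"] = rem

    ds, rem = sample_missingness_filter(ds, cfg.max_sample_missing)
    rep.sample_steps["sample_missingness"] = len(rem)
    rep.removed_sample_ids["sample_missingness"] = rem

    _, mismatched, _ = sex_check(ds)
    keep = [i for i, s in enumerate(ds.sample_ids) if s not in set(mismatched)]
    ds = ds.subset(sample_idx=keep)
    rep.sample_steps["sex_mismatch"] = len(mismatched)
    rep.removed_sample_ids["sex_mismatch"] = mismatched

    non_auto = ds.variants["chromosome"].isin(_NON_AUTOSOMES).values
    rep.snp_steps["non_autosomal"] = int(non_auto.sum())
    rep.removed_snp_ids["non_autosomal"] = list(ds.variants.loc[non_auto, "id"])
    ds = ds.subset(variant_idx=np.where(~non_auto)[0])

    ds, rem = maf_filter(ds, cfg.min_maf, orient=False)
    rep.snp_steps["maf"] = len(rem)
    rep.removed_snp_ids["maf"] = rem

    ds, rem, _ = hwe_filter(ds, cfg.hwe_alpha)
    rep.snp_steps["hwe"] = len(rem)
    rep.removed_snp_ids["hwe"] = rem

    het_out = het_outlier_filter(ds, cfg.het_sd_mult) if ds.n_samples >= 3 else []
    keep = [i for i, s in enumerate(ds.sample_ids) if s not in set(het_out)]
    ds = ds.subset(sample_idx=keep)
    rep.sample_steps["heterozygosity"] = len(het_out)
    rep.removed_sample_ids["heterozygosity"] = het_out

    if ds.n_samples >= 2:
        _, _, rel_out = relatedness(ds, cfg.relatedness_threshold)
    else:
        rel_out = []
    keep = [i for i, s in enumerate(ds.sample_ids) if s not in set(rel_out)]
    ds = ds.subset(sample_idx=keep)
    rep.sample_steps["relatedness"] = len(rel_out)
    rep.removed_sample_ids["relatedness"] = rel_out

    if ds.n_samples > max(2, cfg.mds_components):
        comps = mds_components(ds, min(cfg.mds_components, ds.n_samples - 1))
        anc_idx = ancestry_outlier_filter(comps, cfg.ancestry_sd_mult)
    else:
        anc_idx = []
    anc_out = [ds.sample_ids[i] for i in anc_idx]
    keep = [i for i in range(ds.n_samples) if i not in set(anc_idx)]
    ds = ds.subset(sample_idx=keep)
    rep.sample_steps["ancestry"] = len(anc_out)
    rep.removed_sample_ids["ancestry"] = anc_out

    # orient once, on the final sample set, so the cascade is idempotent
    ds = orient_minor(ds)

    rep.final_snps = ds.n_variants
    rep.final_samples = ds.n_samples
    rep.validate()
    if ds.n_samples == 0:
        raise RuntimeError(f"all samples removed by QC; report: {rep}")
    return ds, rep
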