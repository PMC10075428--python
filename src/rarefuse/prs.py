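"""Polygenic risk scores from pipeline-selected SNPs.

Selection: SNPs whose logistic-regression p is below a threshold (default
0.05) and whose position falls inside a combined-test-significant gene
(Bonferroni, UTR-inclusive boundaries). Weights are the per-allele log
odds ratios from the logistic fit. Loci with OR < 1 are flipped so the
counted ("risk") allele always carries a positive weight.

The score is the mean weighted risk-allele count,

    PRS_i = sum_j dosage_ij * ln(OR_j) / n_loci_i,

with n_loci_i the per-sample count of non-missing selected loci, keeping
scores comparable across missingness patterns.

Caveat by design: when weights are estimated on the scored cohort itself
(the only option without an external cohort), the case/control score
difference is optimistically inflated; the comparison then quantifies
in-sample separation, not out-of-sample prediction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from rarefuse.io_formats import CASE, CONTROL, GeneRegion, GenotypeDataset

logger = logging.getLogger(__name__)


def select_prs_snps(
    assoc: pd.DataFrame,
    combined: pd.DataFrame,
    genes: list[GeneRegion],
    p_thresh: float = 0.05,
) -> pd.DataFrame:
    """Select PRS loci and weights.

    ``assoc`` needs id, chromosome, position, beta, p_logistic;
    ``combined`` needs gene_id and significant. Returns a table with
    snp_id, weight (= |ln OR|), and flip (True when the original OR < 1,
    i.e. the other allele is the risk allele). Empty with a warning when
    no combined-significant gene exists.
    """
    sig_genes = set(combined.loc[combined["significant"], "gene_id"])
    if not sig_genes:
        logger.warning("select_prs_snps: no combined-significant genes; empty selection")
        return pd.DataFrame(columns=["snp_id", "weight", "flip"])
    regions = [g for g in genes if g.gene_id in sig_genes]

    ok = assoc["p_logistic"].notna() & (assoc["p_logistic"] < p_thresh)
    cand = assoc.loc[ok & assoc["beta"].notna()]
    chrom = cand["chromosome"].astype(str).values
    pos = cand["position"].values
    inside = np.zeros(len(cand), dtype=bool)
    for g in regions:
        inside |= (chrom == g.chromosome) & (pos >= g.start) & (pos <= g.end)
    sel = cand.loc[inside]
    return pd.DataFrame({
        "snp_id": sel["id"].values,
        "weight": np.abs(sel["beta"].values),
        "flip": sel["beta"].values < 0,
    }).reset_index(drop=True)


def compute_prs(ds: GenotypeDataset, weights: pd.DataFrame) -> pd.DataFrame:
    """Per-sample PRS over the selected loci.

    ``weights`` is the select_prs_snps output. Flipped loci count the
    other allele (dosage 2 - x). Scores are missing for samples with no
    non-missing selected locus.
    """
    idx = pd.Index(ds.variants["id"])
    cols = idx.get_indexer(weights["snp_id"])
    if (cols < 0).any():
        missing = list(weights.loc[cols < 0, "snp_id"])
        raise KeyError(f"weight SNPs not in dataset: {missing}")
    x = ds.dosage_float()[:, cols]
    flip = weights["flip"].values.astype(bool)
    x[:, flip] = 2.0 - x[:, flip]
    w = weights["weight"].values

    nonmiss = ~np.isnan(x)
    n_used = nonmiss.sum(axis=1)
    contrib = np.where(nonmiss, x * w, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(n_used > 0, contrib / n_used, np.nan)
    return pd.DataFrame({
        "sample_id": ds.sample_ids,
        "phenotype": ds.phenotype,
        "score": score,
        "n_loci_used": n_used,
        "n_loci_missing": len(weights) - n_used,
    })


def compare_prs(scores: pd.DataFrame) -> dict:
    """Compare PRS distributions between cases and controls.

    Primary test: two-sided Wilcoxon rank-sum (normal approximation with
    tie correction); secondary: Welch's t. Requires >= 2 scored samples
    per group. Returns statistics, p-values and per-group summaries.
    """
    sc = scores.dropna(subset=["score"])
    cases = sc.loc[sc["phenotype"] == CASE, "score"].values
    ctrls = sc.loc[sc["phenotype"] == CONTROL, "score"].values
    if len(cases) < 2 or len(ctrls) < 2:
        raise ValueError("need >= 2 scored samples in each group")
    mwu = stats.mannwhitneyu(cases, ctrls, alternative="two-sided", method="asymptotic")
    welch = stats.ttest_ind(cases, ctrls, equal_var=False)
    return {
        "wilcoxon_stat": float(mwu.statistic),
        "wilcoxon_p": float(mwu.pvalue),
        "welch_t": float(welch.statistic),
        "welch_p": float(welch.pvalue),
        "n_cases": int(len(cases)),
        "n_controls": int(len(ctrls)),
        "case_mean": float(np.mean(cases)),
        "control_mean": float(np.mean(ctrls)),
        "case_median": float(np.median(cases)),
        "control_median": float(np.median(ctrls)),
    }


def prs_histogram(scores: pd.DataFrame, path: str) -> None:
    """Overlaid per-group score histograms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sc = scores.dropna(subset=["score"])
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, code in (("controls", CONTROL), ("cases", CASE)):
        vals = sc.loc[sc["phenotype"] == code, "score"]
        ax.hist(vals, bins=20, alpha=0.6, label=label, density=True)
    ax.set_xlabel("polygenic risk score")
    ax.set_ylabel("density")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
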