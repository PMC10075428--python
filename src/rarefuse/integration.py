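"""Gene-level fusion of expression and association evidence.

The combined statistic is the equal-weight Stouffer (weighted-Z) form:
each p-value is converted one-sided to a z-score, Z = Phi^-1(1 - p), and

    Z_s = (Z_exp + Z_assoc) / sqrt(2)  ~  N(0, 1) under the joint null,

with p_combined = 1 - Phi(Z_s). Dividing by sqrt(2) (not 2) is what makes
the null standard normal. Before conversion the expression p-values are
rescaled to share the range of the association p-values, so neither
evidence stream dominates merely because its p-values span a different
range (the two experiments have very different sample sizes). The default
rescaling is a rank-preserving linear map of the p scale onto
[min, max] of the target; quantile and -log10-scale maps are available
behind a strategy flag.

Only genes present with a finite p in both streams are combined; genes
absent from the expression data (e.g. not expressed in the cell lines)
cannot be combined and are flagged, not silently dropped.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from rarefuse.assoc_snp import adjust_pvalues

logger = logging.getLogger(__name__)

SQRT2 = np.sqrt(2.0)
_P_FLOOR, _P_CEIL = 1e-300, 1.0 - 1e-16


def rescale_pvalues(p_source, p_target, strategy: str = "minmax") -> np.ndarray:
    """Rescale source p-values to share the range of the target p-values.

    ``minmax``: rank-preserving linear map of the p scale onto
    [min(target), max(target)]. ``log10``: the same linear map on the
    -log10(p) scale. ``quantile``: map each source p to the target
    empirical quantile of its own rank. All strategies preserve order.
    """
    src = np.asarray(p_source, dtype=float)
    tgt = np.asarray(p_target, dtype=float)
    if src.size == 0 or tgt.size == 0:
        raise ValueError("both p-value lists must be non-empty")
    if np.nanmin(src) <= 0 or np.nanmax(src) > 1 or np.nanmin(tgt) <= 0 or np.nanmax(tgt) > 1:
        raise ValueError("p-values must lie in (0, 1]")
    lo_s, hi_s = np.nanmin(src), np.nanmax(src)
    lo_t, hi_t = np.nanmin(tgt), np.nanmax(tgt)
    if hi_s == lo_s:
        raise ValueError("all source p-values identical; range undefined")

    if strategy == "minmax":
        return lo_t + (src - lo_s) * (hi_t - lo_t) / (hi_s - lo_s)
    if strategy == "log10":
        ls, lt = -np.log10(src), -np.log10(tgt)
        lo_ls, hi_ls = np.nanmin(ls), np.nanmax(ls)
        lo_lt, hi_lt = np.nanmin(lt), np.nanmax(lt)
        mapped = lo_lt + (ls - lo_ls) * (hi_lt - lo_lt) / (hi_ls - lo_ls)
        return 10.0 ** (-mapped)
    if strategy == "quantile":
        order = np.argsort(np.argsort(src, kind="mergesort"), kind="mergesort")
        q = (order + 0.5) / src.size
        return np.quantile(tgt, q)
    raise ValueError(f"unknown rescaling strategy {strategy!r}")


def stouffer_combine(p1: float, p2: float) -> tuple[float, float]:
    """Equal-weight Stouffer combination of two p-values.

    Returns (Z_s, p_combined). Inputs of exactly 0 or 1 are clamped into
    (0, 1) with a warning; non-finite inputs are an error.
    """
    if not (np.isfinite(p1) and np.isfinite(p2)):
        raise ValueError("p-values must be finite")
    if p1 <= 0 or p1 >= 1 or p2 <= 0 or p2 >= 1:
        logger.warning("stouffer_combine: clamping boundary p-values into (0,1)")
    p1 = min(max(p1, _P_FLOOR), _P_CEIL)
    p2 = min(max(p2, _P_FLOOR), _P_CEIL)
    z1 = stats.norm.isf(p1)
    z2 = stats.norm.isf(p2)
    zs = (z1 + z2) / SQRT2
    return float(zs), float(stats.norm.sf(zs))


def combined_gene_table(
    de: pd.DataFrame,
    gene_stats: pd.DataFrame,
    alpha: float = 0.05,
    rescale_strategy: str = "minmax",
) -> pd.DataFrame:
    """Per-gene combined statistic from DE and gene-association tables.

    ``de`` needs gene_id and p_raw; ``gene_stats`` needs gene_id and
    p_gene. Raw (not BH-adjusted) p-values enter the combination. Genes
    with a finite p in both streams are combined after rescaling the
    expression p onto the association p range; the rest are kept with
    ``in_both_datasets = False`` and no combined values. Bonferroni runs
    over the genes actually combined; output is sorted by p_combined.
    """
    merged = pd.merge(
        de[["gene_id", "p_raw"]].rename(columns={"p_raw": "p_exp_raw"}),
        gene_stats[["gene_id", "p_gene"]].rename(columns={"p_gene": "p_assoc"}),
        on="gene_id", how="outer",
    )
    both = np.isfinite(merged["p_exp_raw"]) & np.isfinite(merged["p_assoc"])
    if not both.any():
        raise ValueError("no gene has p-values in both evidence streams")
    merged["in_both_datasets"] = both

    sub = merged.loc[both].copy()
    sub["p_exp_rescaled"] = rescale_pvalues(
        sub["p_exp_raw"].values, sub["p_assoc"].values, strategy=rescale_strategy
    )
    pe = np.clip(sub["p_exp_rescaled"].values, _P_FLOOR, _P_CEIL)
    pa = np.clip(sub["p_assoc"].values, _P_FLOOR, _P_CEIL)
    z_exp = stats.norm.isf(pe)
    z_assoc = stats.norm.isf(pa)
    zs = (z_exp + z_assoc) / SQRT2
    sub["Z_exp"], sub["Z_assoc"], sub["Z_s"] = z_exp, z_assoc, zs
    sub["p_combined"] = stats.norm.sf(zs)
    sub["p_combined_bonf"] = adjust_pvalues(sub["p_combined"], "bonferroni")
    sub["significant"] = sub["p_combined_bonf"] < alpha

    out = merged.merge(
        sub.drop(columns=["p_exp_raw", "p_assoc", "in_both_datasets"]),
        on="gene_id", how="left",
    )
    out["significant"] = out["significant"].fillna(False).astype(bool)
    out = out.sort_values(
        "p_combined", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    cols = ["gene_id", "p_exp_raw", "p_exp_rescaled", "p_assoc", "Z_exp",
            "Z_assoc", "Z_s", "p_combined", "p_combined_bonf",
            "in_both_datasets", "significant"]
    return out[cols]


def combined_scatter_plot(combined: pd.DataFrame, path: str) -> None:
    """Scatter of expression vs association p (log scale), colored by
    combined p — the at-a-glance view of which stream drives each gene."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = combined[combined["in_both_datasets"]]
    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(
        sub["p_exp_raw"], sub["p_assoc"], c=-np.log10(sub["p_combined"]),
        s=12, cmap="viridis",
    )
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("expression p-value")
    ax.set_ylabel("association p-value")
    fig.colorbar(sc, label="-log10 combined p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
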