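"""Per-gene differential expression for a paired pre/post-treatment design.

A deliberately simple negative-binomial Wald pipeline: median-of-ratios
size factors, per-gene method-of-moments dispersion, and an NB
log-linear model with per-line (pairing) intercepts plus a condition
effect, tested by Wald. There is no empirical-Bayes dispersion
shrinkage, LFC shrinkage, outlier filtering, or independent filtering —
the downstream evidence fusion only needs a per-gene p-value and a
direction, and externally computed DE tables can be ingested via
:func:`ingest_de_table` when full-featured results are available.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from rarefuse.io_formats import CountsMatrix, FormatError
from rarefuse.assoc_snp import adjust_pvalues

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)


def size_factors(cm: CountsMatrix) -> np.ndarray:
    """Median-of-ratios library-size factors.

    For genes with all-positive counts, each sample's factor is the
    median of count / geometric-mean-across-samples. Errors if no gene is
    positive in every sample.
    """
    counts = cm.counts
    allpos = (counts > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in all samples; median-of-ratios "
            "undefined (consider a pseudo-reference fallback)"
        )
    sub = counts[allpos].astype(float)
    geo = np.exp(np.log(sub).mean(axis=1))
    return np.median(sub / geo[:, None], axis=0)


def _design(cm: CountsMatrix) -> tuple[np.ndarray, int]:
    """Design matrix: per-line intercepts + post-treatment indicator.

    Returns (X, index of the condition column)."""
    lines = sorted(set(cm.pairing))
    X = np.zeros((len(cm.sample_ids), len(lines) + 1))
    for i, line in enumerate(cm.pairing):
        X[i, lines.index(line)] = 1.0
    X[:, -1] = (cm.condition == "post").astype(float)
    return X, X.shape[1] - 1


def nb_wald_de(cm: CountsMatrix, alpha_bh: float = 0.05) -> pd.DataFrame:
    """Negative-binomial Wald differential expression, post vs pre.

    Per gene: normalize by size factors (as a log offset), fit the paired
    log-linear model, and Wald-test the condition coefficient. The NB
    dispersion is a per-gene method-of-moments estimate on the Pearson
    residuals of a first-pass Poisson fit of the same design (floored at
    1e-8) — estimating it conditional on the fitted means keeps the
    condition/line structure out of the dispersion, which a raw
    across-sample variance would absorb. Because that estimate rests on
    very few residual degrees of freedom, the Wald statistic additionally
    carries a Pearson scale factor from the NB fit and is referred to a
    t distribution with the residual df rather than a normal — without
    this the test is badly anti-conservative at 6 pairs. BH adjustment
    across genes; direction is up/down for BH-significant genes by the
    sign of the log2 fold change, else ns. All-zero genes get missing p
    and direction ns.
    """
    if cm.n_pairs < 3:
        raise ValueError("paired NB Wald test needs >= 3 cell-line pairs")
    sf = size_factors(cm)
    offset = np.log(sf)
    X, cond_ix = _design(cm)
    resid_df = max(X.shape[0] - X.shape[1], 1)

    n_genes = len(cm.gene_ids)
    base_mean = (cm.counts / sf).mean(axis=1)
    lfc = np.full(n_genes, np.nan)
    praw = np.full(n_genes, np.nan)

    for g in range(n_genes):
        y = cm.counts[g].astype(float)
        if (y == 0).all():
            continue
        try:
            pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
            mu = pois.mu
            disp = float(np.sum(((y - mu) ** 2 - mu) / mu**2) / resid_df)
            disp = max(disp, 1e-8)
            model = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=disp),
                offset=offset,
            )
            res = model.fit(start_params=pois.params, scale="X2")
            coef = res.params[cond_ix]
            se = res.bse[cond_ix]
            lfc[g] = coef / LN2
            if res.pearson_chi2 < 1e-8:
                praw[g] = 1.0  # model fits exactly; no evidence of an effect
            elif np.isfinite(se) and se > 0:
                praw[g] = 2.0 * stats.t.sf(abs(coef / se), resid_df)
        except Exception:  # noqa: BLE001 - non-converged gene stays missing
            logger.debug("nb_wald_de: fit failed for gene %s", cm.gene_ids[g])

    pbh = adjust_pvalues(praw, "bh")
    sig = pbh < alpha_bh
    direction = np.where(
        sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns")
    )
    return pd.DataFrame({
        "gene_id": cm.gene_ids,
        "base_mean": base_mean,
        "log2_fold_change": lfc,
        "p_raw": praw,
        "p_bh": pbh,
        "direction": direction,
    })


def ingest_de_table(
    path: str,
    gene_col: str = "gene_id",
    lfc_col: str = "log2_fold_change",
    p_col: str = "p_raw",
    alpha_bh: float = 0.05,
) -> pd.DataFrame:
    """Load an externally computed DE table (e.g. full DESeq2 output).

    BH-adjusted p-values are recomputed internally so downstream stages
    see a consistent adjustment. Duplicated gene ids or p-values outside
    [0,1] are errors.
    """
    tab = pd.read_csv(path, sep="\t")
    for col in (gene_col, lfc_col, p_col):
        if col not in tab.columns:
            raise FormatError(
                f"{path}: expected columns {gene_col!r}, {lfc_col!r}, {p_col!r}"
            )
    if tab[gene_col].duplicated().any():
        dups = tab.loc[tab[gene_col].duplicated(), gene_col].tolist()
        raise FormatError(f"{path}: duplicated gene ids {dups[:5]}")
    p = tab[p_col].astype(float).values
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise FormatError(f"{path}: p-values outside [0,1]")
    lfc = tab[lfc_col].astype(float).values
    pbh = adjust_pvalues(p, "bh")
    sig = pbh < alpha_bh
    direction = np.where(
        sig & (lfc > 0), "up", np.where(sig & (lfc < 0), "down", "ns")
    )
    out = pd.DataFrame({
        "gene_id": tab[gene_col].astype(str).values,
        "base_mean": tab["base_mean"].values if "base_mean" in tab.columns else np.nan,
        "log2_fold_change": lfc,
        "p_raw": p,
        "p_bh": pbh,
        "direction": direction,
    })
    return out
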