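"""Per-SNP case/control association tests.

Two tests per SNP, mirroring the classic single-variant workflow:

* the allelic (1-df Pearson) chi-squared test on the 2x2 allele-count
  table, no continuity correction (PLINK ``--assoc`` behavior);
* logistic regression of case status on dosage with optional covariates
  (e.g. MDS stratification components), fit by IRLS, with a Wald test on
  the dosage coefficient.

Missing genotypes drop the sample for that SNP only (complete-case per
SNP). Multiple-testing adjustment (Bonferroni / Benjamini-Hochberg) is
provided for any p-value vector.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from rarefuse.io_formats import CASE, CONTROL, GenotypeDataset

logger = logging.getLogger(__name__)


def allelic_chisq(ds: GenotypeDataset) -> pd.DataFrame:
    """Allelic chi-squared test per SNP.

    Each sample contributes two alleles to a 2x2 (case/control x
    counted/other allele) table. Returns a DataFrame with the table
    counts, the 1-df statistic, the odds ratio of the counted allele, and
    the p-value. Monomorphic SNPs (a zero table margin) get NaN statistic
    and p with a logged warning.
    """
    pheno = ds.phenotype
    informative = (pheno == CASE) | (pheno == CONTROL)
    case = (pheno == CASE) & informative
    ctrl = (pheno == CONTROL) & informative

    d = ds.dosage_float()
    case_nonmiss = (~np.isnan(d[case])).sum(axis=0)
    ctrl_nonmiss = (~np.isnan(d[ctrl])).sum(axis=0)
    a = np.nansum(d[case], axis=0)  # counted alleles in cases
    b = 2.0 * case_nonmiss - a
    c = np.nansum(d[ctrl], axis=0)
    dd = 2.0 * ctrl_nonmiss - c

    n = a + b + c + dd
    r1, r2 = a + b, c + dd
    c1, c2 = a + c, b + dd
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(denom > 0, n * (a * dd - b * c) ** 2 / denom, np.nan)
        p = stats.chi2.sf(stat, df=1)
        orr = np.where((b > 0) & (c > 0) & (dd > 0), (a * dd) / (b * c), np.nan)
    n_bad = int(np.isnan(stat).sum())
    if n_bad:
        logger.warning("allelic_chisq: %d SNPs monomorphic in the tested samples", n_bad)

    return pd.DataFrame({
        "id": ds.variants["id"].values,
        "chromosome": ds.variants["chromosome"].values,
        "position": ds.variants["position"].values,
        "counted_allele": ds.variants["counted_allele"].values,
        "case_counted": a, "case_other": b,
        "control_counted": c, "control_other": dd,
        "chisq_stat": stat, "odds_ratio": orr, "p_chisq": p,
    })


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 100
):
    """Newton/IRLS for a logistic GLM; returns (beta, se, converged)."""
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        H = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, np.full(k, np.nan), False
        # damped step to tame separation-driven divergence
        if np.max(np.abs(step)) > 10:
            step *= 10 / np.max(np.abs(step))
        beta = beta + step
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    # quasi-separation: explosive coefficients invalidate the Wald test
    if np.max(np.abs(beta)) > 15:
        converged = False
    return beta, se, converged


def logistic_assoc(
    ds: GenotypeDataset, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-SNP logistic regression with optional covariates.

    Fits logit P(case) = b0 + b_g * dosage + covariate terms by IRLS
    (gradient tolerance 1e-8, at most 100 iterations) and reports a Wald
    test on the dosage coefficient. Non-converged or separated fits are
    flagged with missing p. Raises if cases are fewer than the number of
    fitted coefficients.
    """
    pheno = ds.phenotype
    informative = (pheno == CASE) | (pheno == CONTROL)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.shape[0] != ds.n_samples:
            raise ValueError("covariate rows must align with samples")
    n_cov = 0 if covariates is None else covariates.shape[1]
    n_cases = int((pheno == CASE).sum())
    if n_cases < n_cov + 2:
        raise ValueError(
            f"{n_cases} cases cannot support {n_cov} covariates + intercept + dosage"
        )

    d = ds.dosage_float()
    out = np.full((ds.n_variants, 4), np.nan)  # beta, se, p, converged
    for j in range(ds.n_variants):
        x = d[:, j]
        use = informative & ~np.isnan(x)
        y = (pheno[use] == CASE).astype(float)
        cols = [np.ones(use.sum()), x[use]]
        if covariates is not None:
            cols.extend(covariates[use].T)
        X = np.column_stack(cols)
        if y.sum() == 0 or y.sum() == len(y) or np.ptp(x[use]) == 0:
            continue
        beta, se, conv = _irls_logistic(X, y)
        out[j, 0] = beta[1]
        out[j, 1] = se[1]
        if conv and np.isfinite(se[1]) and se[1] > 0:
            z = beta[1] / se[1]
            out[j, 2] = 2.0 * stats.norm.sf(abs(z))
        out[j, 3] = float(conv)

    return pd.DataFrame({
        "id": ds.variants["id"].values,
        "beta": out[:, 0],
        "se_beta": out[:, 1],
        "odds_ratio": np.exp(out[:, 0]),
        "p_logistic": out[:, 2],
        "converged": out[:, 3] == 1.0,
    })


def adjust_pvalues(p, method: str) -> np.ndarray:
    """Multiple-testing adjustment with missing-value passthrough.

    ``bonferroni``: min(1, m*p). ``bh``: Benjamini-Hochberg step-up with
    enforced monotonicity. ``m`` counts only the non-missing p-values, and
    missing entries are restored as missing in place.
    """
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    out = np.full_like(p, np.nan)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if method == "bonferroni":
        out[ok] = np.minimum(1.0, m * pv)
    elif method == "bh":
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / (np.arange(m) + 1.0)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(1.0, adj)
        out[ok] = res
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out


def assoc_table(
    ds: GenotypeDataset, covariates: np.ndarray | None = None
) -> pd.DataFrame:
    """Full per-SNP association table: chi-squared + logistic + adjustments."""
    from rarefuse.qc import counted_allele_freq

    chisq = allelic_chisq(ds)
    logit = logistic_assoc(ds, covariates)
    tab = chisq.merge(logit, on="id", suffixes=("", "_logit"))
    freq = counted_allele_freq(ds)
    tab.insert(4, "maf", np.minimum(freq, 1.0 - freq))
    tab["p_chisq_bh"] = adjust_pvalues(tab["p_chisq"], "bh")
    tab["p_chisq_bonf"] = adjust_pvalues(tab["p_chisq"], "bonferroni")
    tab["p_logistic_bh"] = adjust_pvalues(tab["p_logistic"], "bh")
    tab["p_logistic_bonf"] = adjust_pvalues(tab["p_logistic"], "bonferroni")
    return tab
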