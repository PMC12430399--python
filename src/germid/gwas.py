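"""Single-marker GLM association scan.

For each SNP, fit ordinary least squares of the trait on an intercept plus
the additive dosage (0/1/2), Y = Xb + e, over complete cases, and report the
allele-substitution effect, its standard error, the t statistic and the
two-sided p-value from the t distribution with n - 2 degrees of freedom
(n - 2 - q with q optional covariates). SNPs monomorphic among complete
cases get an undefined (NaN) p. Raw p-value tiers (p < 0.001, p < 0.0001)
label hits; no multiple-testing correction is applied by default, though an
FDR column is available as optional output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import GenotypeMatrix

TIER_STRONG = "p < 0.0001"
TIER_NOMINAL = "p < 0.001"


def glm_scan(
    matrix: GenotypeMatrix,
    trait: np.ndarray | pd.Series,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP OLS scan of one quantitative trait.

    Returns a table with columns snp_id, chrom, pos, beta, se, t, p, n_used.
    ``covariates`` (samples x q) are optional nuisance regressors; default
    model is intercept + dosage only.
    """
    y_all = np.asarray(trait, dtype=float)
    if y_all.shape[0] != matrix.n_samples:
        raise ValueError("trait length does not match sample count")
    finite_y = np.isfinite(y_all)
    if finite_y.sum() >= 1 and np.nanstd(y_all) == 0:
        raise ValueError("trait is constant; association undefined")
    x_all = matrix.dosages_float()
    q = 0 if covariates is None else covariates.shape[1]

    no_missing = finite_y.all() and not np.isnan(x_all).any()
    if no_missing and covariates is None:
        beta, se, tstat, pval, n_used = _scan_complete(x_all, y_all)
    else:
        m = matrix.n_loci
        beta = np.full(m, np.nan)
        se = np.full(m, np.nan)
        tstat = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        n_used = np.zeros(m, dtype=int)
        for j in range(m):
            ok = finite_y & np.isfinite(x_all[:, j])
            if covariates is not None:
                ok &= np.all(np.isfinite(covariates), axis=1)
            n = int(ok.sum())
            n_used[j] = n
            df = n - 2 - q
            if n < 3 or df < 1:
                continue
            xj = x_all[ok, j]
            if np.ptp(xj) == 0:
                continue
            cols = [np.ones(n), xj]
            if covariates is not None:
                cols.extend(covariates[ok].T)
            X = np.column_stack(cols)
            b, res = _ols(X, y_all[ok])
            sigma2 = res / df
            xtx_inv = np.linalg.inv(X.T @ X)
            beta[j] = b[1]
            se[j] = np.sqrt(sigma2 * xtx_inv[1, 1])
            tstat[j] = beta[j] / se[j]
            pval[j] = 2.0 * stats.t.sf(abs(tstat[j]), df)

    return pd.DataFrame(
        {
            "snp_id": matrix.loci["id"].to_numpy(),
            "chrom": matrix.loci["chrom"].to_numpy(),
            "pos": matrix.loci["pos"].to_numpy(),
            "beta": beta,
            "se": se,
            "t": tstat,
            "p": pval,
            "n_used": n_used,
        }
    )


def _ols(X: np.ndarray, y: np.ndarray):
    b, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    return b, float(resid @ resid)


def _scan_complete(x: np.ndarray, y: np.ndarray):
    """Vectorised simple regression across all SNPs (no missing data)."""
    n, m = x.shape
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = np.sum(xc**2, axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)
    poly = sxx > 0
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    df = n - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        beta[poly] = sxy[poly] / sxx[poly]
        rss = syy - beta[poly] ** 2 * sxx[poly]
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        se[poly] = np.sqrt(sigma2 / sxx[poly])
        with np.errstate(invalid="ignore"):
            tstat[poly] = np.where(se[poly] > 0, beta[poly] / se[poly], np.inf * np.sign(beta[poly]))
        pval[poly] = 2.0 * stats.t.sf(np.abs(tstat[poly]), df)
    pval[poly] = np.clip(pval[poly], np.finfo(float).tiny, 1.0)
    return beta, se, tstat, pval, np.full(m, n, dtype=int)


def significant_hits(
    results: pd.DataFrame, threshold: float = 1e-3, trait_name: str | None = None
) -> pd.DataFrame:
    """Hits with p strictly below ``threshold``, labelled with the finest
    tier among {p<0.001, p<0.0001} they satisfy, sorted by p then position."""
    if len(results) == 0:
        raise ValueError("empty result table")
    hits = results[results["p"] < threshold].copy()
    hits["tier"] = np.where(hits["p"] < 1e-4, TIER_STRONG, TIER_NOMINAL)
    if trait_name is not None:
        hits.insert(0, "trait", trait_name)
    hits = hits.sort_values(["p", "chrom", "pos"], kind="stable")
    return hits.reset_index(drop=True)


def fdr_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """Optional Benjamini–Hochberg q-values appended as column ``q``."""
    from statsmodels.stats.multitest import multipletests

    out = results.copy()
    ok = np.isfinite(out["p"].to_numpy())
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok] = multipletests(out["p"].to_numpy()[ok], method="fdr_bh")[1]
    out["q"] = q
    return out


def qq_data(results: pd.DataFrame) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p sorted ascending; expected quantiles i/(m+1).
    """
    p = results["p"].to_numpy(dtype=float)
    p = np.sort(p[np.isfinite(p)])
    if p.size == 0:
        raise ValueError("no defined p-values")
    m = p.size
    expected = np.arange(1, m + 1) / (m + 1)
    return pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p)}
    )


def manhattan_data(results: pd.DataFrame) -> pd.DataFrame:
    """Cumulative genome coordinate, -log10 p and chromosome parity per SNP."""
    out = results.copy()
    offsets = {}
    offset = 0
    chroms = list(dict.fromkeys(out["chrom"]))
    for c in chroms:
        offsets[c] = offset
        offset += int(out.loc[out["chrom"] == c, "pos"].max())
    out["coord"] = [offsets[c] + p for c, p in zip(out["chrom"], out["pos"])]
    out["neglog10p"] = -np.log10(out["p"])
    parity = {c: i % 2 for i, c in enumerate(chroms)}
    out["parity"] = [parity[c] for c in out["chrom"]]
    out.attrs["total_span"] = offset
    return out
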