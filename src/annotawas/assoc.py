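"""Per-variant association testing and quality control.

The scan fits, for each variant j,

    y = a + b * dosage_j + sum_k c_k * covariate_k + e

and reports the Wald two-sided p-value for b.  Covariates are the dosages of
already-accepted lead SNPs, which is how the conditional rounds of the QTL
scan are run.  The default engine is ordinary least squares, vectorized by
residualizing phenotype and dosages on the covariates once and then doing a
simple regression per variant.  An optional mixed-model engine ("lmm")
estimates a polygenic variance component once under the null (GRM from
standardized dosages, REML over the variance ratio on eigen-rotated data) and
then runs the same vectorized machinery on whitened data — generalized least
squares with the variance components held fixed.

P-values are computed on the log scale throughout; ``neglog10p`` never
underflows even when ``p`` does.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats

_LN10 = np.log(10.0)
_MAX_NEGLOG10P = -np.log10(np.finfo(float).tiny)  # ≈ 307.65


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy–Weinberg 1-df chi-square goodness-of-fit p-value.

    Expected genotype proportions come from the sample allele frequency.
    Monomorphic samples return p = 1 by convention.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_AA + n_Aa) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def variant_maf(dosages: np.ndarray) -> np.ndarray:
    """Minor allele frequency per variant from mean dosage, folded to ≤ 0.5."""
    freq = np.asarray(dosages).mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def qc_filter(genotypes, maf_min: float = 0.01, hwe_min: float = 1e-6) -> np.ndarray:
    """Boolean mask of variants passing MAF and HWE filters.

    A variant is kept iff its MAF is at least ``maf_min`` and its HWE
    p-value at least ``hwe_min``.  HWE uses genotype counts from dosages
    rounded to the nearest integer (fractional imputed dosages are tolerated).
    """
    dosages = genotypes.dosages
    maf = variant_maf(dosages)
    keep = maf >= maf_min
    for j in np.flatnonzero(keep):
        geno = np.rint(dosages[:, j]).astype(int).clip(0, 2)
        counts = np.bincount(geno, minlength=3)
        # counts are ref-homozygote, het, alt-homozygote
        if hwe_test(counts[0], counts[1], counts[2]) < hwe_min:
            keep[j] = False
    return keep


def tukey_filter(values) -> np.ndarray:
    """Mask of records inside Tukey's fences [Q1 − 1.5·IQR, Q3 + 1.5·IQR].

    Quartiles use linear interpolation between order statistics.  Fences are
    inclusive, so a constant vector keeps every record.  Fewer than 4 values
    pass through unfiltered with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        warnings.warn("fewer than 4 values; Tukey filter is a no-op")
        return np.ones(values.size, dtype=bool)
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return (values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)


def _design(n: int, covariates) -> np.ndarray:
    """Intercept + covariates, dropping columns that add no rank.

    A zero or redundant covariate (e.g. a lead SNP conditioned on twice)
    must not change any result, including residual degrees of freedom.
    """
    kept = [np.ones(n)]
    if covariates is not None:
        for cov in covariates:
            col = np.asarray(cov, dtype=float)
            Q, _ = np.linalg.qr(np.column_stack(kept))
            resid = col - Q @ (Q.T @ col)
            if resid @ resid > 1e-10 * max(col @ col, 1.0):
                kept.append(col)
    return np.column_stack(kept)


def _scan_core(G: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Simple regression of y on each column of G after projecting out C.

    Returns (beta, se, p, neglog10p, flags).  Requires centered/whitened
    inputs as prepared by the callers.
    """
    n, m = G.shape
    df = n - C.shape[1] - 1
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)

    var_raw = G.var(axis=0)
    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    yy = float(y_res @ y_res)

    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    nlp = np.full(m, np.nan)
    flags = np.array([""] * m, dtype=object)

    monomorphic = var_raw <= 0
    # collinear with covariates: essentially no variance left after projection
    collinear = (~monomorphic) & (gg <= 1e-10 * n * np.maximum(var_raw, 1e-300))
    ok = ~(monomorphic | collinear)
    flags[monomorphic] = "monomorphic"
    flags[collinear] = "collinear"
    p[collinear] = 1.0
    nlp[collinear] = 0.0
    beta[collinear] = 0.0

    idx = np.flatnonzero(ok)
    if idx.size:
        b = gy[idx] / gg[idx]
        rss = yy - b * gy[idx]
        rss = np.maximum(rss, 0.0)
        boundary = rss <= 1e-12 * max(yy, 1e-300)
        sigma2 = rss / df
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.sqrt(sigma2 / gg[idx])
            t = np.where(s > 0, b / s, np.inf)
        logp = np.log(2.0) + stats.t.logsf(np.abs(t), df)
        neglog10 = np.minimum(-logp / _LN10, _MAX_NEGLOG10P)
        neglog10[boundary] = _MAX_NEGLOG10P
        pv = np.power(10.0, -neglog10)
        pv = np.clip(pv, np.finfo(float).tiny, 1.0)
        beta[idx] = b
        se[idx] = s
        p[idx] = pv
        nlp[idx] = neglog10
        bflags = flags[idx]
        bflags[boundary] = "boundary"
        flags[idx] = bflags
    return beta, se, p, nlp, flags


def _reml_whiten(dosages: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Fit the null LMM once and return the whitening transform.

    GRM = ZZ'/m from column-standardized dosages; REML maximizes over the
    residual-to-genetic variance ratio delta on eigen-rotated data.  Returns
    (U, weights) such that multiplying rotated vectors by 1/sqrt(weights)
    yields homoskedastic errors.
    """
    sd = dosages.std(axis=0)
    use = sd > 0
    Z = (dosages[:, use] - dosages[:, use].mean(axis=0)) / sd[use]
    K = (Z @ Z.T) / Z.shape[1]
    eigvals, U = np.linalg.eigh(K)
    eigvals = np.maximum(eigvals, 0.0)
    y_rot = U.T @ y
    C_rot = U.T @ C
    n, c = C.shape

    def neg_reml(log10_delta: float) -> float:
        delta = 10.0**log10_delta
        w = eigvals + delta
        Cw = C_rot / np.sqrt(w)[:, None]
        yw = y_rot / np.sqrt(w)
        coef, _, _, _ = np.linalg.lstsq(Cw, yw, rcond=None)
        rss = float(((yw - Cw @ coef) ** 2).sum())
        sign, logdet = np.linalg.slogdet(Cw.T @ Cw)
        return 0.5 * ((n - c) * np.log(rss) + np.log(w).sum() + logdet)

    res = optimize.minimize_scalar(neg_reml, bounds=(-4.0, 4.0), method="bounded")
    delta = 10.0**res.x
    return U, eigvals + delta


def assoc_scan(
    genotypes,
    phenotype,
    covariate_dosages=None,
    model: str = "ols",
    round_index: int = 1,
) -> pd.DataFrame:
    """Scan every variant for association with the phenotype.

    Parameters
    ----------
    genotypes : GenotypeMatrix
    phenotype : array of length n_samples
    covariate_dosages : list of arrays, optional
        Dosage vectors of conditioning lead SNPs.
    model : "ols" or "lmm"
    round_index : recorded in the ``round`` column (1 = unconditional).

    Returns a DataFrame with columns chrom, pos, id, ref, alt, maf, beta, se,
    p, neglog10p, round, flags.
    """
    y = np.asarray(phenotype, dtype=float)
    n = genotypes.n_samples
    if y.shape[0] != n:
        raise ValueError("phenotype length does not match sample count")
    n_cov = 0 if covariate_dosages is None else len(covariate_dosages)
    if n <= 2 + n_cov:
        raise ValueError(f"need more than {2 + n_cov} samples for {n_cov} covariates")
    C = _design(n, covariate_dosages)
    G = genotypes.dosages
    if model == "lmm":
        U, w = _reml_whiten(G, y, C)
        sw = np.sqrt(w)[:, None]
        var_raw = G.var(axis=0)  # monomorphism judged pre-rotation
        Gw = (U.T @ G) / sw
        # re-inject raw variance so the monomorphic flag survives rotation
        beta, se, p, nlp, flags = _scan_core_with_varmask(
            Gw, (U.T @ y) / sw.ravel(), (U.T @ C) / sw, var_raw
        )
    elif model == "ols":
        beta, se, p, nlp, flags = _scan_core(G, y, C)
    else:
        raise ValueError(f"unknown model {model!r}; expected 'ols' or 'lmm'")
    out = genotypes.variants.copy()
    out["maf"] = variant_maf(G)
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["neglog10p"] = nlp
    out["round"] = round_index
    out["flags"] = flags
    return out


def _scan_core_with_varmask(G, y, C, var_raw):
    beta, se, p, nlp, flags = _scan_core(G, y, C)
    mono = var_raw <= 0
    beta[mono], se[mono], p[mono], nlp[mono] = np.nan, np.nan, np.nan, np.nan
    flags[mono] = "monomorphic"
    return beta, se, p, nlp, flags
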