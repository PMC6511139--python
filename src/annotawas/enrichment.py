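"""Maximum-likelihood category enrichment from QTL candidate sets.

Model: each QTL harbors exactly one causal variant hidden among its candidate
set.  A candidate of annotation category C is causal with a per-variant rate
λ_C relative to the genome-wide average, constrained by the genomic category
frequencies f_C = T_C / T so that Σ_C λ_C f_C = 1.  Writing n_qC for the
number of category-C candidates of QTL q, the likelihood is

    L(λ) = Π_q Σ_C n_qC · λ_C    subject to  Σ_C λ_C f_C = 1.

EM with the causal variant's category as the latent variable:

  E-step:  r_qC = n_qC λ_C / Σ_C' n_qC' λ_C'
  M-step:  π_C = (1/Q) Σ_q r_qC,   λ_C = π_C / f_C

(the M-step is the Lagrange solution of the constrained weighted-log
maximization, so the constraint holds exactly after every iteration).

λ_C at convergence is the category's enrichment e_C — the probability that a
causal variant is of category C divided by C's genomic frequency.  The
log-likelihood is non-decreasing at every iteration (standard EM guarantee;
asserted in the test suite).

Confidence intervals come from resampling the QTL list with replacement and
re-estimating; the default interval is the normal approximation
point ± 1.96 × bootstrap SD (a percentile option is available).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import CategoryCensus

EM_TOL = 1e-8
EM_MAX_ITER = 10_000


def qtl_category_counts(signals, categories_by_variant, scheme) -> pd.DataFrame:
    """Build the QTL × category candidate-count matrix.

    ``categories_by_variant`` maps variant id → category label (for the given
    scheme).  Returns a DataFrame with one row per QTL and one column per
    scheme category.
    """
    from .annotation import get_scheme

    scheme = get_scheme(scheme)
    rows = []
    index = []
    for i, sig in enumerate(signals):
        counts = dict.fromkeys(scheme.categories, 0)
        for vid in sig.candidates:
            cat = categories_by_variant[vid]
            counts[cat] += 1
        rows.append(counts)
        index.append(f"{sig.trait or 'trait'}:{sig.lead_id}" if hasattr(sig, "lead_id") else i)
    df = pd.DataFrame(rows, index=index, columns=list(scheme.categories))
    if len(df) and (df.sum(axis=1) < 1).any():
        raise ValueError("every QTL needs at least one candidate")
    return df


def em_enrichment(counts: np.ndarray, frequency: np.ndarray,
                  tol: float = EM_TOL, max_iter: int = EM_MAX_ITER,
                  return_trace: bool = False):
    """Run the constrained EM; returns (pi, lam) or (pi, lam, loglik_trace).

    ``counts`` is Q × C; ``frequency`` the genomic fractions f_C (sum 1).
    Categories with candidates but zero genomic frequency are an error;
    categories absent from every candidate set converge to π_C = 0.
    """
    counts = np.asarray(counts, dtype=float)
    f = np.asarray(frequency, dtype=float)
    Q, C = counts.shape
    if Q == 0:
        raise ValueError("no QTL")
    present = counts.sum(axis=0) > 0
    if np.any(present & (f <= 0)):
        raise ValueError("category with candidates but zero genomic frequency")
    lam = np.ones(C)
    lam[f <= 0] = 0.0
    trace = []
    for _ in range(max_iter):
        mix = counts * lam[None, :]  # n_qC · λ_C
        denom = mix.sum(axis=1, keepdims=True)
        if np.any(denom <= 0):
            raise ValueError("QTL with zero likelihood under every category")
        trace.append(float(np.log(denom).sum()))
        resp = mix / denom
        pi = resp.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_lam = np.where(f > 0, pi / f, 0.0)
        if np.max(np.abs(new_lam - lam)) < tol:
            lam = new_lam
            break
        lam = new_lam
    pi = lam * f
    if return_trace:
        return pi, lam, trace
    return pi, lam


def estimate_enrichment(qtl_counts: pd.DataFrame, census: CategoryCensus) -> pd.DataFrame:
    """Point estimates of π_C and e_C.

    Returns a DataFrame indexed by category with columns ``n_candidates``,
    ``pi`` and ``enrichment``.
    """
    cats = list(census.scheme.categories)
    counts = qtl_counts.reindex(columns=cats, fill_value=0)
    if len(counts) == 0:
        raise ValueError("empty QTL list")
    pi, lam = em_enrichment(counts.to_numpy(), census.frequency.to_numpy())
    return pd.DataFrame(
        dict(
            n_candidates=counts.sum(axis=0).astype(int),
            pi=pi,
            enrichment=lam,
        ),
        index=pd.Index(cats, name="category"),
    )


def bootstrap_enrichment(
    qtl_counts: pd.DataFrame,
    census: CategoryCensus,
    n_boot: int = 100,
    seed: int = 0,
    ci: str = "normal",
):
    """Point estimates with bootstrap confidence intervals.

    The QTL list is resampled with replacement ``n_boot`` times and the EM
    re-run on each resample.  ``ci`` = "normal" gives estimate ± 1.96·SD of
    the bootstrap distribution (symmetric; can dip below 0), "percentile" the
    2.5/97.5 empirical quantiles.  Returns ``(table, replicates)`` where
    ``replicates`` is the n_boot × categories enrichment matrix.
    """
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    if ci not in ("normal", "percentile"):
        raise ValueError(f"unknown ci method {ci!r}")
    est = estimate_enrichment(qtl_counts, census)
    rng = np.random.default_rng(seed)
    Q = len(qtl_counts)
    f = census.frequency.to_numpy()
    arr = qtl_counts.reindex(columns=list(census.scheme.categories), fill_value=0).to_numpy()
    reps = np.empty((n_boot, arr.shape[1]))
    for b in range(n_boot):
        take = rng.integers(0, Q, size=Q)
        _, lam = em_enrichment(arr[take], f)
        reps[b] = lam
    boot_mean = reps.mean(axis=0)
    boot_se = reps.std(axis=0, ddof=1)
    point = est["enrichment"].to_numpy()
    if ci == "normal":
        lo = point - 1.96 * boot_se
        hi = point + 1.96 * boot_se
    else:
        lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    table = est.copy()
    table["boot_mean"] = boot_mean
    table["boot_se"] = boot_se
    table["ci_low"] = lo
    table["ci_high"] = hi
    replicates = pd.DataFrame(reps, columns=est.index, index=pd.RangeIndex(n_boot, name="replicate"))
    return table, replicates
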