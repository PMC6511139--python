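"""Iterative conditional QTL detection and LD candidate extraction.

Per chromosome: an unconditional scan (round 1) finds the strongest variant;
if its −log10(p) exceeds the genome-wide threshold its dosage is fitted as a
covariate and the chromosome is rescanned, repeatedly, until no further
variant is significant.  A later-round lead is accepted only if it was also
significant in round 1.  A lead that is the only significant variant within
±1 Mb is treated as a likely artefact (false positive or misplaced marker)
and dropped from the QTL list, though by default it is still conditioned on
so the scan can move past it.

Each accepted QTL gets a candidate causal set: all same-chromosome variants
with r² to the lead above ``r2_min`` (strict) that were themselves
genome-wide significant in round 1, plus the lead itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import assoc_scan

DEFAULT_THRESHOLD = 8.5
DEFAULT_R2_MIN = 0.2
DEFAULT_WINDOW_BP = 1_000_000
MAX_ROUNDS = 50


@dataclass
class QTLSignal:
    """One detected association signal."""

    lead_id: str
    chrom: str
    pos: int
    round: int
    lead_neglog10p: float
    conditioned_on: list[str] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    candidate_r2: dict = field(default_factory=dict)
    trait: str = ""
    lone: bool = False


def ld_r2(dosage_a, dosage_b) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Allele-coding invariant (d → 2−d leaves r² unchanged).  Constant vectors
    have undefined correlation; 0 is returned by convention.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if a.size < 3:
        raise ValueError("need at least 3 samples for r²")
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_r2_with_lead(dosages: np.ndarray, lead_col: int) -> np.ndarray:
    """Vector of r² between every column and the lead column."""
    lead = dosages[:, lead_col]
    centered = dosages - dosages.mean(axis=0)
    lc = lead - lead.mean()
    denom = np.sqrt(np.einsum("ij,ij->j", centered, centered)) * np.sqrt(lc @ lc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, centered.T @ lc / denom, 0.0)
    return r * r


def find_lead(results: pd.DataFrame, threshold_neglog10: float = DEFAULT_THRESHOLD):
    """Index (in ``results``) of the top variant if genome-wide significant.

    Ties on −log10(p) break by smaller position, then lexicographic id.
    Returns None when nothing exceeds the threshold.
    """
    if len(results) == 0:
        return None
    nlp = results["neglog10p"].to_numpy()
    valid = np.isfinite(nlp)
    if not valid.any():
        return None
    best = np.nanmax(nlp[valid])
    if not best > threshold_neglog10:
        return None
    tied = results.index[np.isclose(nlp, best) & valid]
    tied_rows = results.loc[tied]
    order = tied_rows.sort_values(["pos", "id"]).index
    return order[0]


def is_lone_lead(
    lead_row,
    results: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    threshold_neglog10: float = DEFAULT_THRESHOLD,
) -> bool:
    """True iff no *other* significant variant lies within ±window (inclusive)."""
    same_chrom = results["chrom"].astype(str) == str(lead_row["chrom"])
    near = (results["pos"] >= lead_row["pos"] - window_bp) & (
        results["pos"] <= lead_row["pos"] + window_bp
    )
    sig = results["neglog10p"] > threshold_neglog10
    others = same_chrom & near & sig & (results["id"] != lead_row["id"])
    return not bool(others.any())


def candidate_set(
    lead_row,
    round1_results: pd.DataFrame,
    genotypes,
    r2_min: float = DEFAULT_R2_MIN,
    threshold_neglog10: float = DEFAULT_THRESHOLD,
):
    """Candidate causal variants for one QTL.

    Same-chromosome variants with r² to the lead strictly above ``r2_min``
    whose *round-1* −log10(p) exceeds the threshold, plus the lead.
    Returns ``(ids, r2_by_id)``.
    """
    chrom_mask = (genotypes.variants["chrom"].astype(str) == str(lead_row["chrom"])).to_numpy()
    ids = genotypes.variants["id"].astype(str).to_numpy()
    lead_col = int(np.flatnonzero(ids == str(lead_row["id"]))[0])
    r2 = ld_r2_with_lead(genotypes.dosages, lead_col)

    nlp = (
        round1_results.set_index("id")["neglog10p"]
        .reindex(ids)
        .to_numpy()
    )
    with np.errstate(invalid="ignore"):
        keep = chrom_mask & (r2 > r2_min) & (np.nan_to_num(nlp, nan=-1.0) > threshold_neglog10)
    keep[lead_col] = True
    cand_ids = [str(v) for v in ids[keep]]
    r2_by_id = {str(v): float(x) for v, x in zip(ids[keep], r2[keep])}
    return cand_ids, r2_by_id


def detect_qtl_chromosome(
    genotypes,
    phenotype,
    threshold_neglog10: float = DEFAULT_THRESHOLD,
    r2_min: float = DEFAULT_R2_MIN,
    window_bp: int = DEFAULT_WINDOW_BP,
    model: str = "ols",
    condition_on_lone: bool = True,
    trait: str = "",
) -> list[QTLSignal]:
    """Run the iterative conditional scan on one chromosome.

    ``genotypes`` must already be QC-filtered and restricted to a single
    chromosome.  Returns accepted QTL in detection order; lone leads are
    excluded from the list (and, when ``condition_on_lone``, still added to
    the conditioning set so the scan continues past them).
    """
    chroms = genotypes.chromosomes()
    if len(chroms) != 1:
        raise ValueError(f"expected one chromosome, got {chroms}")
    ids = genotypes.variants["id"].to_numpy()

    round1 = assoc_scan(genotypes, phenotype, model=model, round_index=1)
    round1_nlp = round1.set_index("id")["neglog10p"]
    results = round1
    signals: list[QTLSignal] = []
    conditioning: list[str] = []
    covariates: list[np.ndarray] = []

    for rnd in range(1, MAX_ROUNDS + 1):
        lead_idx = find_lead(results, threshold_neglog10)
        if lead_idx is None:
            return signals
        lead_row = results.loc[lead_idx]
        if rnd > 1 and not round1_nlp.get(lead_row["id"], -np.inf) > threshold_neglog10:
            # a conditional-only signal with no unconditional support ends the scan
            return signals
        lone = is_lone_lead(lead_row, results, window_bp, threshold_neglog10)
        lead_col = int(np.flatnonzero(ids == lead_row["id"])[0])
        if not lone:
            cand_ids, r2_by_id = candidate_set(
                lead_row, round1, genotypes, r2_min, threshold_neglog10
            )
            signals.append(
                QTLSignal(
                    lead_id=str(lead_row["id"]),
                    chrom=str(lead_row["chrom"]),
                    pos=int(lead_row["pos"]),
                    round=rnd,
                    lead_neglog10p=float(lead_row["neglog10p"]),
                    conditioned_on=list(conditioning),
                    candidates=cand_ids,
                    candidate_r2=r2_by_id,
                    trait=trait,
                    lone=False,
                )
            )
        if lone and not condition_on_lone:
            return signals
        conditioning.append(str(lead_row["id"]))
        covariates.append(genotypes.dosages[:, lead_col].copy())
        results = assoc_scan(
            genotypes, phenotype, covariate_dosages=covariates, model=model,
            round_index=rnd + 1,
        )
    raise RuntimeError(f"conditional scan did not converge in {MAX_ROUNDS} rounds")


def detect_qtl(
    genotypes,
    phenotype,
    threshold_neglog10: float = DEFAULT_THRESHOLD,
    **kwargs,
) -> list[QTLSignal]:
    """Run :func:`detect_qtl_chromosome` over every chromosome."""
    signals = []
    for chrom in genotypes.chromosomes():
        mask = (genotypes.variants["chrom"] == chrom).to_numpy()
        sub = genotypes.subset_variants(mask)
        signals.extend(
            detect_qtl_chromosome(sub, phenotype, threshold_neglog10, **kwargs)
        )
    return signals


def deduplicate_candidates(signals: list[QTLSignal]) -> list[QTLSignal]:
    """Assign a variant appearing in several QTLs' candidate sets to the QTL
    with which it has the larger r² (leads always stay with their own QTL)."""
    best: dict[str, tuple[float, int]] = {}
    for i, sig in enumerate(signals):
        for vid in sig.candidates:
            r2 = 2.0 if vid == sig.lead_id else sig.candidate_r2.get(vid, 0.0)
            if vid not in best or r2 > best[vid][0]:
                best[vid] = (r2, i)
    out = []
    for i, sig in enumerate(signals):
        kept = [v for v in sig.candidates if best[v][1] == i]
        if sig.lead_id not in kept:
            kept.append(sig.lead_id)
        out.append(
            QTLSignal(
                lead_id=sig.lead_id,
                chrom=sig.chrom,
                pos=sig.pos,
                round=sig.round,
                lead_neglog10p=sig.lead_neglog10p,
                conditioned_on=list(sig.conditioned_on),
                candidates=kept,
                candidate_r2={v: sig.candidate_r2.get(v, 1.0) for v in kept},
                trait=sig.trait,
                lone=sig.lone,
            )
        )
    return out


def qtl_table(signals: list[QTLSignal]) -> pd.DataFrame:
    """Summary table, one row per QTL."""
    return pd.DataFrame(
        [
            dict(
                trait=s.trait,
                chrom=s.chrom,
                lead_id=s.lead_id,
                lead_pos=s.pos,
                round=s.round,
                lead_neglog10p=s.lead_neglog10p,
                n_candidates=len(s.candidates),
            )
            for s in signals
        ],
        columns=[
            "trait", "chrom", "lead_id", "lead_pos", "round",
            "lead_neglog10p", "n_candidates",
        ],
    )


def candidate_table(signals: list[QTLSignal], round1_results=None) -> pd.DataFrame:
    """Long table, one row per (QTL, candidate)."""
    nlp = None
    if round1_results is not None:
        nlp = round1_results.set_index("id")["neglog10p"]
    rows = []
    for i, s in enumerate(signals):
        for vid in s.candidates:
            rows.append(
                dict(
                    qtl_id=f"{s.trait or 'trait'}:{s.lead_id}",
                    variant_id=vid,
                    r2=1.0 if vid == s.lead_id else s.candidate_r2.get(vid, np.nan),
                    round1_neglog10p=float(nlp.get(vid, np.nan)) if nlp is not None else np.nan,
                )
            )
    return pd.DataFrame(rows, columns=["qtl_id", "variant_id", "r2", "round1_neglog10p"])
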