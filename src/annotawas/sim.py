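"""Synthetic genomes, annotations and phenotypes for pipeline testing.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* **Genotypes** — a block-mosaic copying model.  Each LD block holds K founder
  haplotypes; the allele at a variant with drawn frequency p is carried by the
  first ``round(K·p)`` founders (at least one), so variants of similar
  frequency share founder columns and are in strong LD.  Each sample haplotype walks
  along the block copying one founder, switching founders with a small
  per-variant probability, plus a small mutation rate.  Founder choice is
  independent across blocks, so between-block r² is at the level expected for
  independent variants (≈ 1/(n−1)).
* **Annotations** — each variant draws one of the eight functional categories
  (high/moderate/low impact, UTR, OC, RE, ncRNA, NKI) from configurable
  genomic frequencies; consequence terms and interval memberships are then
  constructed so the classifier reproduces the drawn category exactly.
* **Phenotypes** — causal variants are sampled without replacement with
  probability proportional to a per-category enrichment multiplier; additive
  effects are standard normal, jointly rescaled so the genetic variance
  fraction equals the requested heritability; residuals are i.i.d. normal.

Everything is deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from .annotation import EIGHT
from .io_formats import (
    GenotypeMatrix,
    IntervalSet,
    write_bed,
    write_table,
    write_vcf,
    write_vep_table,
)

#: consequence term used to induce each category; modifier categories get
#: their category from interval membership instead.
_CATEGORY_TERM = {
    ann.HIGH: "stop_gained",
    ann.MODERATE: "missense_variant",
    ann.LOW: "synonymous_variant",
    ann.UTR: "intergenic_variant",
    ann.OC: "intergenic_variant",
    ann.RE: "intergenic_variant",
    ann.NCRNA: "intergenic_variant",
    ann.NKI: "intergenic_variant",
}
_CATEGORY_INTERVAL = {ann.UTR: "utr", ann.OC: "oc", ann.RE: "re", ann.NCRNA: "ncrna"}

_DEFAULT_FREQUENCIES = {
    ann.HIGH: 0.0005,
    ann.MODERATE: 0.005,
    ann.LOW: 0.02,
    ann.UTR: 0.005,
    ann.OC: 0.03,
    ann.RE: 0.05,
    ann.NCRNA: 0.002,
    ann.NKI: 0.8875,
}


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    ``category_frequencies`` are genomic fractions of the eight-category
    scheme and must sum to 1; ``causal_enrichment`` multiplies each category's
    per-variant chance of being causal (categories not listed default to 1).
    """

    n_samples: int = 1000
    n_variants: int = 10000
    n_chromosomes: int = 5
    ld_block_size: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    category_frequencies: dict = field(default_factory=lambda: dict(_DEFAULT_FREQUENCIES))
    causal_enrichment: dict = field(default_factory=dict)
    n_causal: int = 20
    heritability: float = 0.5
    seed: int = 0
    # mosaic model knobs
    n_founders: int = 16
    switch_rate: float = 0.02
    mutation_rate: float = 0.005
    spacing_bp: int = 1000

    def __post_init__(self):
        self.maf_range = tuple(self.maf_range)
        total = sum(self.category_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category_frequencies must sum to 1 (got {total})")
        if any(f < 0 for f in self.category_frequencies.values()):
            raise ValueError("category_frequencies must be non-negative")
        unknown = set(self.category_frequencies) - set(EIGHT.categories)
        if unknown:
            raise ValueError(f"unknown categories {sorted(unknown)}")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError("heritability must be in [0, 1]")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal exceeds n_variants")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low ≤ high ≤ 0.5")
        if any(m < 0 for m in self.causal_enrichment.values()):
            raise ValueError("causal_enrichment multipliers must be ≥ 0")

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        data["maf_range"] = list(self.maf_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def _child_rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(stream + 1)[stream])


def variant_frame(config: SimConfig) -> pd.DataFrame:
    """Deterministic variant coordinates: equal split over chromosomes."""
    per_chrom = np.full(config.n_chromosomes, config.n_variants // config.n_chromosomes)
    per_chrom[: config.n_variants % config.n_chromosomes] += 1
    rows = []
    for c, n in enumerate(per_chrom, start=1):
        for i in range(n):
            pos = (i + 1) * config.spacing_bp
            rows.append(dict(chrom=str(c), pos=pos, id=f"chr{c}:{pos}", ref="A", alt="G"))
    return pd.DataFrame(rows)


def simulate_annotated_genome(config: SimConfig):
    """Generate the annotation landscape.

    Returns ``(variants, terms_by_variant, interval_sets, categories)`` where
    ``categories`` is the induced eight-category label per variant (a pandas
    Series aligned with ``variants``).  Interval sets are per-variant
    single-base features so classification is exact by construction.
    """
    rng = _child_rng(config, 1)
    variants = variant_frame(config)
    cats = list(config.category_frequencies)
    probs = np.array([config.category_frequencies[c] for c in cats], dtype=float)
    draw = rng.choice(len(cats), size=len(variants), p=probs / probs.sum())
    categories = pd.Series([cats[i] for i in draw], index=variants.index, name="cat8")

    terms_by_variant: dict[str, set] = {}
    interval_sets = {name: IntervalSet(name) for name in ann.INTERVAL_CLASSES}
    for (_, row), cat in zip(variants.iterrows(), categories):
        terms_by_variant[row.id] = {_CATEGORY_TERM[cat]}
        iv_class = _CATEGORY_INTERVAL.get(cat)
        if iv_class is not None:
            interval_sets[iv_class].add(row.chrom, row.pos, row.pos)
    return variants, terms_by_variant, interval_sets, categories


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw diploid dosages under the block-mosaic copying model."""
    if config.n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = _child_rng(config, 0)
    variants = variant_frame(config)
    n_hap = 2 * config.n_samples
    K = config.n_founders
    lo, hi = config.maf_range
    dosage_blocks = []
    for chrom in pd.unique(variants["chrom"]):
        m_chrom = int((variants["chrom"] == chrom).sum())
        for start in range(0, m_chrom, config.ld_block_size):
            L = min(config.ld_block_size, m_chrom - start)
            p = rng.uniform(lo, hi, size=L)
            # founder allele count tracks the drawn frequency; ≥1 so no
            # variant is monomorphic among founders.  Variants of equal
            # frequency share identical founder columns (maximal LD).
            k = np.clip(np.rint(K * p).astype(int), 1, K - 1)
            founders = np.arange(K)[:, None] < k[None, :]  # (K, L)
            # founder index path per haplotype: switch to a random founder
            # with prob switch_rate, independently per variant
            switch = rng.random((n_hap, L)) < config.switch_rate
            switch[:, 0] = True
            candidate = rng.integers(0, K, size=(n_hap, L))
            last = np.maximum.accumulate(
                np.where(switch, np.arange(L)[None, :], -1), axis=1
            )
            idx = candidate[np.arange(n_hap)[:, None], last]
            alleles = founders[idx, np.arange(L)[None, :]]
            flip = rng.random((n_hap, L)) < config.mutation_rate
            alleles = alleles ^ flip
            dosage_blocks.append(
                alleles[: config.n_samples].astype(float)
                + alleles[config.n_samples :].astype(float)
            )
    dosages = np.concatenate(dosage_blocks, axis=1)
    samples = [f"S{i:05d}" for i in range(config.n_samples)]
    return GenotypeMatrix(dosages, samples, variants)


def simulate_phenotypes(
    genotypes: GenotypeMatrix, categories: pd.Series, config: SimConfig
):
    """Draw one quantitative trait; returns ``(phenotype, truth)``.

    Causal variants are sampled without replacement with probability
    proportional to ``causal_enrichment[category]``; the truth table records
    their ids, rescaled effect sizes and categories.
    """
    if len(categories) != genotypes.n_variants:
        raise ValueError("category assignment does not cover all variants")
    rng = _child_rng(config, 2)
    weights = np.array(
        [config.causal_enrichment.get(c, 1.0) for c in categories], dtype=float
    )
    if weights.sum() <= 0:
        raise ValueError("causal_enrichment leaves no sampleable variant")
    causal_idx = rng.choice(
        genotypes.n_variants, size=config.n_causal, replace=False, p=weights / weights.sum()
    )
    effects = rng.standard_normal(config.n_causal)
    residual = rng.standard_normal(genotypes.n_samples)

    h2 = config.heritability
    X = genotypes.dosages[:, causal_idx]
    g = (X - X.mean(axis=0)) @ effects
    if h2 == 0.0 or config.n_causal == 0:
        phenotype = residual
        scaled_effects = np.zeros_like(effects)
    else:
        sd_g = g.std()
        if sd_g == 0:
            raise ValueError("zero genetic variance with nonzero heritability")
        scale_g = np.sqrt(h2) / sd_g
        g = g * scale_g
        scaled_effects = effects * scale_g
        if h2 == 1.0:
            phenotype = g
        else:
            e = residual / residual.std() * np.sqrt(1.0 - h2)
            phenotype = g + e
    truth = pd.DataFrame(
        dict(
            causal_variant_id=genotypes.variants["id"].iloc[causal_idx].to_numpy(),
            effect_size=scaled_effects,
            category=categories.iloc[causal_idx].to_numpy(),
        )
    )
    return phenotype, truth


def simulate_study(config: SimConfig):
    """Convenience wrapper: genotypes + annotations + one phenotype.

    Returns a dict with keys ``genotypes, variants, terms, intervals,
    categories, phenotype, truth``.
    """
    variants, terms, intervals, categories = simulate_annotated_genome(config)
    genotypes = simulate_genotypes(config)
    phenotype, truth = simulate_phenotypes(genotypes, categories, config)
    return dict(
        genotypes=genotypes,
        variants=variants,
        terms=terms,
        intervals=intervals,
        categories=categories,
        phenotype=phenotype,
        truth=truth,
    )


def write_study(study: dict, outdir) -> None:
    """Write a simulated study to disk in the pipeline's input formats."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gm: GenotypeMatrix = study["genotypes"]
    write_vcf(gm, outdir / "genotypes.vcf")
    pheno = pd.DataFrame(dict(sample_id=gm.samples, value=study["phenotype"]))
    write_table(pheno, outdir / "phenotypes.tsv")
    write_vep_table(study["terms"], outdir / "annotations.tsv")
    for name, iset in study["intervals"].items():
        write_bed(iset, outdir / f"{name}.bed")
    write_table(study["truth"], outdir / "truth.tsv")


def induced_assignment(study: dict) -> pd.DataFrame:
    """Recompute the classifier's assignment table from the simulated inputs."""
    variants = study["variants"]
    memberships = pd.DataFrame(
        {
            name: iset.contains_many(variants["chrom"], variants["pos"])
            for name, iset in study["intervals"].items()
        },
        index=variants["id"].to_numpy(),
    )
    return ann.assign_categories(variants["id"], study["terms"], memberships)
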