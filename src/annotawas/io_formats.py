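"""Readers and writers for the formats the pipeline touches.

Coordinate convention: 1-based inclusive everywhere internally (the VCF/VEP
convention).  BED's 0-based half-open intervals are converted at the boundary:
a BED line ``chrom 99 200`` becomes the internal interval chrom:100-200.

Genotypes are held as a samples × variants dosage matrix on the 0-2 alt-dose
scale.  Dosage comes from the VCF ``DS`` FORMAT field when present, otherwise
from the alt-allele count in ``GT``; missing genotypes are mean-imputed per
variant and flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples × variants dosages with variant coordinates.

    ``dosages[i, j]`` is the alt-allele dose of sample i at variant j.
    ``missing_rate`` is the per-variant fraction of genotypes that were
    missing in the source and mean-imputed.
    """

    dosages: np.ndarray
    samples: list[str]
    variants: pd.DataFrame  # columns chrom, pos, id, ref, alt
    missing_rate: np.ndarray = field(default=None)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples × variants)")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError("sample count mismatch")
        if m != len(self.variants):
            raise ValueError("variant count mismatch")
        self.variants = self.variants.reset_index(drop=True)
        if self.missing_rate is None:
            self.missing_rate = np.zeros(m)
        key = self.variants[["chrom", "pos", "ref", "alt"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, ref, alt) variant keys")
        if (self.variants["pos"] < 1).any():
            raise ValueError("positions must be ≥ 1")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.samples,
            self.variants.iloc[idx],
            self.missing_rate[idx],
        )

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.variants["chrom"]))


class IntervalSet:
    """Named set of genomic intervals, 1-based inclusive, with overlap query."""

    def __init__(self, name: str, intervals=()):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if end < start:
            raise ValueError(f"interval end < start: {chrom}:{start}-{end}")
        # intervaltree is half-open; store [start, end+1)
        self._trees.setdefault(str(chrom), IntervalTree()).addi(start, end + 1)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(str(chrom))
        return bool(tree is not None and tree.overlaps_point(pos))

    def contains_many(self, chroms, positions) -> np.ndarray:
        return np.array([self.contains(c, p) for c, p in zip(chroms, positions)])

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def to_records(self) -> list[tuple[str, int, int]]:
        recs = []
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                recs.append((chrom, iv.begin, iv.end - 1))
        return recs


def read_vcf_dosages(path, max_missing: float = 0.10):
    """Read a VCF into a :class:`GenotypeMatrix`.

    DS is preferred over GT where both are present.  Missing genotypes are
    mean-imputed per variant; variants missing in more than ``max_missing``
    of samples are dropped with a warning.  Multi-allelic records are skipped
    with a warning (the pipeline accepts bi-allelic records only).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")
    try:
        vcf.get_header_type("DS")
        header_has_ds = True
    except KeyError:
        header_has_ds = False
    rows, dosage_cols, missing_rates = [], [], []
    has_any_field = False
    for rec in vcf:
        if len(rec.ALT) != 1:
            warnings.warn(f"{path}: skipping non-bi-allelic record {rec.CHROM}:{rec.POS}")
            continue
        ds = rec.format("DS") if header_has_ds else None
        if ds is not None:
            has_any_field = True
            dose = np.asarray(ds, dtype=float).reshape(-1)
            miss = ~np.isfinite(dose)
        else:
            gts = rec.genotype.array()  # columns: allele1, allele2, phased
            if gts is None:
                continue
            has_any_field = True
            alleles = gts[:, :2].astype(float)
            miss = (alleles < 0).any(axis=1)
            dose = alleles.clip(min=0).sum(axis=1)
        rate = miss.mean()
        if rate > max_missing:
            warnings.warn(
                f"{path}: dropping {rec.CHROM}:{rec.POS} ({rate:.0%} missing genotypes)"
            )
            continue
        if miss.any():
            observed = dose[~miss]
            dose = dose.copy()
            dose[miss] = observed.mean() if observed.size else 0.0
        rows.append(
            dict(
                chrom=rec.CHROM,
                pos=rec.POS,
                id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                ref=rec.REF,
                alt=rec.ALT[0],
            )
        )
        dosage_cols.append(dose)
        missing_rates.append(rate)
    if rows and not has_any_field:
        raise ValueError(f"{path}: VCF records carry neither GT nor DS")
    if not rows:
        raise ValueError(f"{path}: no usable bi-allelic records")
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    return GenotypeMatrix(dosages, samples, pd.DataFrame(rows), np.array(missing_rates))


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write integer dosages as a minimal GT-only VCF (text, uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in gm.variants.iterrows():
            doses = np.rint(gm.dosages[:, j]).astype(int).clip(0, 2)
            gts = "\t".join(gt_codes[d] for d in doses)
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_bed_intervals(path, name: str) -> IntervalSet:
    """Read a 3+ column BED file; 0-based half-open → 1-based inclusive."""
    iset = IntervalSet(name)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected ≥3 tab-separated columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: BED end ≤ start ({start}, {end})")
            iset.add(chrom, start + 1, end)
    return iset


def write_bed(iset: IntervalSet, path) -> None:
    """Write an interval set as BED (internal 1-based inclusive → 0-based half-open)."""
    with open(path, "w") as fh:
        for chrom, start, end in iset.to_records():
            fh.write(f"{chrom}\t{start - 1}\t{end}\n")


def read_vep_table(path, known_variants=None) -> dict[str, set]:
    """Collect consequence term sets per variant from VEP tabular output.

    Multiple rows per variant (one per transcript) are merged.  The variant
    key is the first column (``#Uploaded_variation`` in stock VEP output).
    Variants absent from ``known_variants`` (if given) are retained with a
    warning so the genome census stays complete.
    """
    df = pd.read_csv(path, sep="\t", comment=None, dtype=str)
    first = df.columns[0]
    cons_col = next((c for c in df.columns if c.lower() == "consequence"), None)
    if cons_col is None:
        raise ValueError(f"{path}: no Consequence column")
    terms: dict[str, set] = {}
    for vid, cons in zip(df[first], df[cons_col]):
        term_set = terms.setdefault(str(vid), set())
        if isinstance(cons, str):
            term_set.update(t.strip() for t in cons.split(",") if t.strip())
    if known_variants is not None:
        extra = set(terms) - set(known_variants)
        if extra:
            warnings.warn(
                f"{path}: {len(extra)} annotated variants absent from the genotype set"
            )
    return terms


def write_vep_table(terms_by_variant: dict[str, set], path) -> None:
    with open(path, "w") as fh:
        fh.write("#Uploaded_variation\tConsequence\n")
        for vid, terms in terms_by_variant.items():
            fh.write(f"{vid}\t{','.join(sorted(terms))}\n")


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a results table as TSV, floats at 12 significant digits, NA literal."""
    df.to_csv(path, sep="\t", index=index, float_format="%.12g", na_rep="NA")


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True, **kwargs)
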