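"""Simulate the synthetic cohort and archive its input files.

Writes the genotype VCF, the VEP-style annotation table, the four interval
BEDs, and per-trait phenotype + causal-truth tables under
results/analysis/study/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from study_utils import CONFIG, build_cohort  # noqa: E402

import pandas as pd  # noqa: E402

from annotawas.io_formats import write_bed, write_table, write_vcf, write_vep_table  # noqa: E402

cohort = build_cohort()
out = CONFIG["STUDY_DIR"]
out.mkdir(parents=True, exist_ok=True)

write_vcf(cohort["genotypes"], out / "genotypes.vcf")
write_vep_table(cohort["terms"], out / "annotations.tsv")
for name, iset in cohort["intervals"].items():
    write_bed(iset, out / f"{name}.bed")
for trait, y, truth in cohort["traits"]:
    pheno = pd.DataFrame(dict(sample_id=cohort["genotypes"].samples, value=y))
    write_table(pheno, out / f"phenotype_{trait}.tsv")
    write_table(truth, out / f"truth_{trait}.tsv")

n_mod = sum((truth["category"] == "moderate").sum() for _, _, truth in cohort["traits"])
n_tot = sum(len(truth) for _, _, truth in cohort["traits"])
print(f"cohort: {cohort['genotypes'].n_samples} samples × "
      f"{cohort['genotypes'].n_variants} variants, {len(cohort['traits'])} traits")
print(f"causal variants of moderate impact: {n_mod}/{n_tot} "
      f"(genomic frequency {CONFIG['CATEGORY_FREQUENCIES']['moderate']})")
print(f"written to {out}")
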