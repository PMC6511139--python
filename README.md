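# annotawas

Annotation-weighted significance thresholds for genome-wide association
studies of quantitative traits.

A flat Bonferroni correction treats every one of T tested variants as equally
likely to be causal. In dense (sequence-level) GWAS panels that is clearly
false: missense variants, UTR variants or open-chromatin variants are far more
often causal per variant than anonymous intergenic ones. `annotawas`
implements the full procedure for exploiting that structure in a livestock
(or any quantitative-trait) GWAS:

1. **Conditional QTL detection** — per chromosome, the strongest variant with
   −log₁₀(p) above the genome-wide threshold is taken as a lead SNP, fitted as
   a covariate, and the chromosome rescanned until nothing remains
   significant. A later-round lead must also have been significant in round 1;
   a lead that is the *only* significant variant within ±1 Mb is treated as a
   likely artefact and dropped.
2. **LD candidate extraction** — for each QTL, every same-chromosome variant
   with r² > 0.2 to the lead that was itself genome-wide significant in
   round 1 becomes a candidate causal variant.
3. **Annotation classification** — each variant gets exactly one category in
   three nested schemes built from VEP consequence impacts and interval
   annotations (open chromatin, UTR, predicted regulatory elements, ncRNA):
   4 categories (high/moderate/low/other), 5 (other → OC/NKF) and
   8 (NKF → UTR/RE/ncRNA/NKI, with UTR taking precedence over OC).
4. **Enrichment estimation** — assuming one causal variant per QTL, hidden in
   its candidate set, the per-variant causal rate λ_C of category C maximizes

   L(λ) = Π_q Σ_C n_qC · λ_C subject to Σ_C λ_C · (T_C / T) = 1,

   solved by EM. λ_C is the *enrichment* e_C: the probability that a causal
   variant is of category C divided by C's genomic frequency. 95% CIs come
   from bootstrap resampling of the QTL list (100 resamples).
5. **Weighted Bonferroni thresholds** — each category's per-test threshold is
   P_wt,C = P_bc · w_C with w_C = e_C / ((1/T) Σ_C' T_C' e_C') and
   P_bc = α/T, so Σ_C T_C w_C = T and the total α budget is conserved.
   Non-enriched categories (e_C ≤ 1) keep the flat threshold. Power under
   flat vs weighted thresholds is compared on the same scan.

Real sequence-level cattle data are access-restricted, so the package ships a
first-class synthetic-data generator: LD-block genotypes from a
founder-haplotype mosaic, an annotation landscape with configurable category
frequencies, and phenotypes whose causal variants are preferentially drawn
from chosen categories — giving ground truth for every downstream stage.

## Worked example

The numbered scripts under `analysis/` run a pooled multi-trait study:
1,000 samples × 10,000 variants, 8 traits with h² = 0.6 whose 15 causal
variants each are drawn with a 20-fold preference for missense variants.

```sh
python analysis/01_simulate_study.py
python analysis/02_map_qtl.py
python analysis/03_estimate_enrichment.py
python analysis/04_weighted_thresholds.py
python analysis/05_power_experiment.py
```

Script 02 prints

```
genome-wide threshold: -log10(p) > 5.30
pooled QTL over 8 traits: 56; pooled candidates: 560 (547 unique)
QTL whose candidate set contains a true causal variant: 55/56
```

— the conditional scan found 56 association signals, and the LD clumping
almost always captured the true causal variant. Script 03 then recovers the
planted enrichment from candidate-set composition alone:

```
moderate-impact enrichment 12.09 (95% CI 5.01 to 19.17); implied true per-variant rate ≈ 14.5
```

and script 05 shows the headline comparison — category-weighted thresholds
never lose power and sometimes gain it:

```
weighted ≥ flat in 20/20 replicates (strictly better in 5); mean power 0.463 flat vs 0.480 weighted
```

The same pipeline is available as subcommands over arbitrary VCF + phenotype
+ VEP + BED inputs:

```sh
annotawas all --config config.yaml          # or any single stage:
annotawas simulate|gwas|detect-qtl|candidates|annotate|enrich|thresholds|apply ...
```

## Layout

- `src/annotawas/` — the library: `sim` (synthetic data), `io_formats` (VCF /
  BED / VEP / TSV), `assoc` (QC + association scans), `qtl` (conditional
  detection + LD candidates), `annotation` (category schemes + census),
  `enrichment` (EM + bootstrap), `thresholds` (weights + power comparison),
  `cli` (stage orchestration).
- `analysis/` — numbered narrative drivers of the synthetic study.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
- `tests/` — unit, property and end-to-end acceptance tests.
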