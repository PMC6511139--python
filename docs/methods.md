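# Methods

## Association model

The default engine fits, per variant j,

    y = a + b·d_j + Σ_k c_k·x_k + e,        e ~ N(0, σ²)

by ordinary least squares, where d_j is the alt-allele dosage (0–2; fractional
imputed dosages accepted) and the x_k are dosages of already-accepted lead
SNPs — conditioning in the iterative QTL scan is literally "fit the lead as a
covariate and rescan". The Wald two-sided p-value for b is reported. The scan
is vectorized: phenotype and all dosages are residualized on the covariate
design once (QR), after which each variant needs only a simple regression.
Covariate columns that add no rank (a zero vector, a duplicated lead) are
dropped so that degenerate conditioning cannot change results.

An optional mixed-model engine (`model: lmm`) guards against confounding by
relatedness: a GRM built from column-standardized dosages, one REML
maximization of the residual-to-genetic variance ratio on eigen-rotated data
under the null model, then per-variant generalized least squares with the
variance components held fixed (whitening by 1/√(s_i + δ) reduces it to the
same vectorized machinery). With unrelated samples and no polygenic signal it
collapses onto OLS (tested). OLS is the default because it is exact, fast at
desk scale, and the synthetic cohorts have no family structure.

P-values are handled on the log scale throughout; `neglog10p` is exact even
where `p` underflows. A perfect fit (zero residual) is flagged `boundary` and
reported at the smallest representable p; variants collinear with the
conditioning set are flagged and given p = 1.

### Quality control

Variants are kept iff MAF ≥ 0.01 (from mean dosage/2, folded) and the 1-df
chi-square Hardy–Weinberg goodness-of-fit p ≥ 1e−6 (genotype counts from
dosages rounded to integers; monomorphic variants get p = 1 by convention).
Phenotypes can optionally be filtered by Tukey's rule (outside quartiles
± 1.5·IQR removed; quartiles by linear interpolation, fences inclusive).

## QTL detection and candidate sets

Per chromosome, round 1 is the unconditional scan. While the top variant
exceeds the genome-wide threshold its dosage joins the covariate set and the
chromosome is rescanned; a round-k lead (k ≥ 2) is accepted only if it also
exceeded the threshold in round 1 — a conditional-only signal with no
unconditional support ends the scan. Ties on −log₁₀(p) break by smaller
position, then lexicographic id. A lead with no other significant variant
within ±1 Mb (inclusive window) is a *lone lead*: excluded from the QTL list
as a probable artefact, but by default still conditioned on
(`condition_on_lone`) so the scan can move past it — the alternative
(stopping at a lone lead) is available as a flag. A hard cap of 50 rounds
guards against non-convergence.

Candidates of a QTL are the same-chromosome variants with r² strictly greater
than 0.2 to the lead (squared Pearson correlation of dosages) whose *round-1*
−log₁₀(p) exceeds the threshold, plus the lead. Round-1 p-values are used for
all QTL, including later-round leads, as the common reference. A variant
qualifying for several QTL is kept only in the QTL with which it has the
largest r²; leads are never reassigned. QTL lists from multiple traits are
concatenated before enrichment, so a variant may appear once per trait.

The genome-wide threshold defaults to −log₁₀(α/T) for the T post-QC variants
(the flat Bonferroni point; ≈ 8.5 at α = 0.05 and T = 16.5 M), and can be
fixed in the config instead.

## Annotation categories

VEP consequence terms are mapped to impacts (HIGH > MODERATE > LOW >
MODIFIER) and the most severe impact per variant retained. One deliberate
deviation from stock VEP: `upstream_gene_variant` and
`downstream_gene_variant` are classed LOW, placing cis-proximal variants with
the functional low-impact class rather than the anonymous bin; the impact map
is a plain dict (loadable from YAML) so stock semantics can be restored.

Classification is an ordered partition; impact classes HIGH/MODERATE/LOW are
never reassigned by interval membership.

- FOUR: high / moderate / low / other.
- FIVE: "other" (modifier) split by open chromatin — OC if inside the union
  of ATAC-seq, H3K27Ac and H3K4me3 peak sets, else NKF.
- EIGHT: NKF refined with precedence **UTR > OC > RE > ncRNA > NKI** for
  modifier variants. UTR-before-OC is intentional: untranslated regions carry
  a specific molecular function (translation initiation/termination), whereas
  open chromatin is tissue-conditional evidence; a modifier variant in both
  is therefore a UTR variant in the eight-way scheme while remaining OC in
  the five-way one.

The category census (T, T_C) is taken over *all* variants passing QC, not
just candidates — it is the denominator of both the enrichment and the
weights.

## Enrichment estimation

Model: each QTL harbors exactly one causal variant hidden among its
candidates, and a candidate of category C is causal with per-variant rate
λ_C relative to the genome-wide average. With n_qC the candidate counts and
f_C = T_C/T,

    L(λ) = Π_q Σ_C n_qC·λ_C,   subject to Σ_C λ_C·f_C = 1.

Candidates are treated exchangeably within a QTL (no LD-weighting toward the
lead). EM with the causal category as latent variable: responsibilities
r_qC ∝ n_qC λ_C; the constrained M-step is the Lagrange solution
π_C = mean_q r_qC, λ_C = π_C/f_C, so the constraint holds exactly after every
iteration and the log-likelihood is non-decreasing (asserted in tests).
Initialization λ = 1 (the constraint-satisfying no-enrichment point);
convergence at max|Δλ| < 1e−8 or 10,000 iterations. e_C = λ_C at convergence;
categories absent from every candidate set get e_C = 0 (not NA), so the
downstream e ≤ 1 rule applies uniformly. For two categories the EM solution
matches a 1-D zoomed grid search of the constrained likelihood to 1e−4.

### Bootstrap confidence intervals

The QTL list is resampled with replacement (Q draws, 100 resamples by
default) and the EM re-run per resample. The default interval is the normal
approximation, point ± 1.96 × bootstrap SD — symmetric, and allowed to dip
below zero for near-zero estimates; a percentile option exists. Known
limitation: with few signal-bearing QTL the point estimate can collapse to
the zero boundary, where the symmetric interval under-covers (at ~5 expected
signal QTL, measured coverage was ≈ 75% rather than 95%; at ~10 it is
nominal). Resampling is unstratified across traits.

## Weighted thresholds

w_C = e_C / ((1/T)·Σ_C' T_C'·e_C'), giving Σ_C T_C·w_C = T identically, and
P_wt,C = P_bc·w_C with P_bc = α/T. The normalizer sums over *all* categories
including non-enriched ones (default; an `enriched-only` variant lets
non-enriched categories contribute unit mass instead). When the enrichments
come from the EM under the same census, the normalizer equals 1 exactly —
the EM constraint is the same sum — so w_C = e_C; the general formula matters
when enrichments and census come from different sources. Categories with
e_C ≤ 1 keep the flat threshold and are reported NA — the trigger is the
point estimate, not the CI. This fallback makes the realized per-test budget
Σ T_C·(applied threshold) ≥ α; the inflation is reported as a diagnostic,
not corrected, matching the procedure's intent that non-enriched categories
are simply left at the conventional threshold.

Thresholds in reports are printed at full precision in TSV; the
proportionality P_wt,A/P_wt,B = e_A/e_B holds to 1e−12 and is the basis for
recomputing published per-category thresholds from published enrichments.

## Synthetic data

The generator supplies the statistical structure the pipeline assumes, with
ground truth:

- **Genotypes** (block-mosaic copying): each LD block of `ld_block_size`
  consecutive variants holds K = 16 founder haplotypes; a variant with drawn
  frequency p (uniform in `maf_range`) has its allele carried by the first
  round(K·p) founders (≥ 1), so similar-frequency variants share founder
  columns and are in strong LD — equal-frequency variants under pure copying
  have r² = 1. Each sample haplotype walks along the block copying one
  founder, switching founders with probability 0.02 per variant and mutating
  with probability 0.005; founder choice is independent across blocks, so
  between-block r² sits at the independence level 1/(n−1). Dosages are
  integer diploid (imputed fractional dosages are read, not generated). A
  coalescent simulator would be more realistic but is not needed to test
  this pipeline; the mosaic model has directly tunable r².
- **Annotations**: each variant draws one eight-way category from
  configurable genomic frequencies; consequence terms and single-base
  interval memberships are constructed so the classifier reproduces the
  drawn category exactly. Default frequencies put ~0.05% of variants in the
  high-impact class and ~89% in NKI, qualitatively mirroring a sequenced
  genome.
- **Phenotypes**: causal variants sampled without replacement with
  probability ∝ a per-category multiplier m_C (the implied per-variant rate
  is m_C / Σ m·f, ≈ m_C when the enriched class is rare); effects standard
  normal, then genetic values and residuals rescaled so the sample genetic
  variance fraction equals h² exactly ("many genes of small effect" is the
  regime of interest). One trait per run; multi-trait studies use one seed
  per trait on the same genome.

What the generator does **not** emulate: imputation error, relatedness /
family structure, heteroskedastic de-regressed-proof weights, realistic
bovine demography or allele-frequency spectra, and LD between annotation
class and allele frequency. Passing tests therefore validate the procedure's
internal logic and statistical calibration, not its behaviour under those
real-data complications.

## Problem sizes and numerical choices

Simulated studies in the tests, analysis scripts and acceptance script use
200–1,000 samples and 1,500–10,000 variants over 3–5 chromosomes, with 20
replicates where distributional claims are made — large enough for the
asymptotics being tested, small enough to run on a laptop in minutes. The
null-calibration experiments use `ld_block_size = 1` (independent variants)
so that KS uniformity applies to the joint set of tests. Seeds are explicit
everywhere; identical configuration reproduces outputs byte-for-byte.
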