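"""Shared configuration for the numbered analysis scripts.

One synthetic cohort at desk scale: 1,000 samples genotyped at 10,000
variants in 20-variant LD blocks over 5 chromosomes, and 8 quantitative
traits simulated on the same genome (h² = 0.6, 15 causal variants each).
Causal variants are drawn with a 20-fold preference for missense
(moderate-impact) variants — the latent per-category enrichment the pipeline
should rediscover from the pooled QTL of all traits, mirroring a multi-trait
dairy-cattle association study pooled for enrichment estimation.

Category frequencies are chosen so the rarer functional classes still hold
tens to hundreds of variants at this genome size; with the 20-fold causal
preference the implied per-variant rate for the moderate class is
λ = 20 / (20·0.02 + 0.98) ≈ 14.5.
"""

from pathlib import Path

from annotawas.sim import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
STUDY_DIR = RESULTS / "study"

SEED = 2026
N_TRAITS = 8
SCHEME = "EIGHT"
ALPHA = 0.05
N_BOOT = 100

CATEGORY_FREQUENCIES = {
    "high": 0.001,
    "moderate": 0.02,
    "low": 0.03,
    "UTR": 0.01,
    "OC": 0.04,
    "RE": 0.06,
    "ncRNA": 0.004,
    "NKI": 0.835,
}

BASE = SimConfig(
    n_samples=1000,
    n_variants=10_000,
    n_chromosomes=5,
    n_causal=15,
    heritability=0.6,
    causal_enrichment={"moderate": 20.0},
    category_frequencies=CATEGORY_FREQUENCIES,
    seed=SEED,
)
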