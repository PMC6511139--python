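"""Helpers shared by the numbered analysis scripts.

Every script is standalone: the cohort is re-derived deterministically from
the seeds in 00_config rather than re-read from disk, so each step can be
rerun in isolation and still agree byte-for-byte with the archived tables.
"""

import runpy
from dataclasses import replace
from pathlib import Path

import pandas as pd

from annotawas.assoc import qc_filter
from annotawas.sim import simulate_annotated_genome, simulate_genotypes, simulate_phenotypes

CONFIG = runpy.run_path(Path(__file__).parent / "00_config.py")


def build_cohort():
    """Genome + QC'd genotypes + per-trait phenotypes/truths, deterministic."""
    base = CONFIG["BASE"]
    variants, terms, intervals, cats8 = simulate_annotated_genome(base)
    gm = simulate_genotypes(base)
    keep = qc_filter(gm)
    gm_qc = gm.subset_variants(keep)
    cats_by_id = pd.Series(cats8[keep].to_numpy(), index=gm_qc.variants["id"])
    traits = []
    for t in range(CONFIG["N_TRAITS"]):
        cfg_t = replace(base, seed=CONFIG["SEED"] + t)
        y, truth = simulate_phenotypes(gm, cats8, cfg_t)
        traits.append((f"t{t}", y, truth))
    return dict(
        base=base, variants=variants, terms=terms, intervals=intervals,
        cats8=cats8, genotypes=gm, genotypes_qc=gm_qc, cats_by_id=cats_by_id,
        traits=traits,
    )
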