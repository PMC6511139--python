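"""Variant annotation categories.

Maps VEP consequence terms plus interval memberships (open chromatin, UTR,
predicted regulatory elements, ncRNA) onto three nested category schemes:

* FOUR:  high / moderate / low impact, everything else "other".
* FIVE:  "other" split by open chromatin into OC and NKF (no known function).
* EIGHT: NKF split further into UTR, RE, ncRNA and NKI (no known information),
  with UTR taking precedence over OC for modifier variants that are in both.

The impact map follows the VEP severity table with one deliberate deviation:
``upstream_gene_variant`` and ``downstream_gene_variant`` are classed LOW
(stock VEP calls them MODIFIER) so that cis-proximal variants land in the
low-impact category rather than the unannotated bin.  The map is exposed as a
plain dict and can be replaced wholesale (e.g. loaded from YAML) to restore
stock VEP semantics.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
import yaml

IMPACT_LEVELS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {lvl: i for i, lvl in enumerate(IMPACT_LEVELS)}

#: consequence term -> impact.  Terms not listed default to MODIFIER.
DEFAULT_IMPACT_MAP: dict[str, str] = {
    # HIGH
    "transcript_ablation": "HIGH",
    "splice_acceptor_variant": "HIGH",
    "splice_donor_variant": "HIGH",
    "stop_gained": "HIGH",
    "frameshift_variant": "HIGH",
    "stop_lost": "HIGH",
    "start_lost": "HIGH",
    "transcript_amplification": "HIGH",
    # MODERATE
    "inframe_insertion": "MODERATE",
    "inframe_deletion": "MODERATE",
    "missense_variant": "MODERATE",
    "protein_altering_variant": "MODERATE",
    # LOW
    "splice_region_variant": "LOW",
    "incomplete_terminal_codon_variant": "LOW",
    "start_retained_variant": "LOW",
    "stop_retained_variant": "LOW",
    "synonymous_variant": "LOW",
    # deliberate deviation from stock VEP: cis-proximal variants are LOW here
    "upstream_gene_variant": "LOW",
    "downstream_gene_variant": "LOW",
    # MODIFIER (explicit common terms; anything unknown also maps here)
    "coding_sequence_variant": "MODIFIER",
    "mature_miRNA_variant": "MODIFIER",
    "5_prime_UTR_variant": "MODIFIER",
    "3_prime_UTR_variant": "MODIFIER",
    "non_coding_transcript_exon_variant": "MODIFIER",
    "intron_variant": "MODIFIER",
    "NMD_transcript_variant": "MODIFIER",
    "non_coding_transcript_variant": "MODIFIER",
    "TFBS_ablation": "MODIFIER",
    "TFBS_amplification": "MODIFIER",
    "TF_binding_site_variant": "MODIFIER",
    "regulatory_region_variant": "MODIFIER",
    "regulatory_region_ablation": "MODIFIER",
    "regulatory_region_amplification": "MODIFIER",
    "feature_elongation": "MODIFIER",
    "feature_truncation": "MODIFIER",
    "intergenic_variant": "MODIFIER",
}

# Category labels
HIGH, MODERATE, LOW = "high", "moderate", "low"
OTHER, OC, NKF = "other", "OC", "NKF"
UTR, RE, NCRNA, NKI = "UTR", "RE", "ncRNA", "NKI"

#: interval class labels in the order the classifier consults them
INTERVAL_CLASSES = ("oc", "utr", "re", "ncrna")


@dataclass(frozen=True)
class CategoryScheme:
    """An ordered partition rule assigning each variant exactly one label."""

    name: str
    categories: tuple[str, ...]

    def __contains__(self, label: str) -> bool:
        return label in self.categories


FOUR = CategoryScheme("FOUR", (HIGH, MODERATE, LOW, OTHER))
FIVE = CategoryScheme("FIVE", (HIGH, MODERATE, LOW, OC, NKF))
EIGHT = CategoryScheme("EIGHT", (HIGH, MODERATE, LOW, UTR, OC, RE, NCRNA, NKI))

SCHEMES = {s.name: s for s in (FOUR, FIVE, EIGHT)}


def get_scheme(name: str | CategoryScheme) -> CategoryScheme:
    if isinstance(name, CategoryScheme):
        return name
    try:
        return SCHEMES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown category scheme {name!r}; expected one of {list(SCHEMES)}")


def load_impact_map(path) -> dict[str, str]:
    """Load a consequence→impact map from a YAML/JSON file."""
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    bad = {t: i for t, i in mapping.items() if i not in IMPACT_LEVELS}
    if bad:
        raise ValueError(f"invalid impact levels in map: {bad}")
    return dict(mapping)


def impact_rank(consequence_terms, impact_map: dict[str, str] | None = None) -> str:
    """Return the most severe impact among a variant's consequence terms.

    When a variant carries multiple annotations (one per transcript) the
    highest impact is retained, ordered HIGH > MODERATE > LOW > MODIFIER.
    Unknown terms map to MODIFIER with a warning; an empty term set likewise.
    """
    impact_map = DEFAULT_IMPACT_MAP if impact_map is None else impact_map
    terms = list(consequence_terms)
    if not terms:
        warnings.warn("variant with no consequence terms; assigning MODIFIER")
        return "MODIFIER"
    best = "MODIFIER"
    for term in terms:
        if term not in impact_map:
            warnings.warn(f"unknown consequence term {term!r}; treating as MODIFIER")
        impact = impact_map.get(term, "MODIFIER")
        if _IMPACT_RANK[impact] < _IMPACT_RANK[best]:
            best = impact
    return best


def classify(impact: str, memberships, scheme: str | CategoryScheme) -> str:
    """Assign one category label given a variant's impact and interval flags.

    ``memberships`` maps interval class (``oc``/``utr``/``re``/``ncrna``) to
    bool.  Impact classes HIGH/MODERATE/LOW are never reassigned by intervals.
    For MODIFIER variants the EIGHT scheme applies the precedence
    UTR > OC > RE > ncRNA > NKI; FIVE only distinguishes OC from NKF.
    """
    scheme = get_scheme(scheme)
    if impact not in IMPACT_LEVELS:
        raise ValueError(f"invalid impact {impact!r}")
    if impact == "HIGH":
        return HIGH
    if impact == "MODERATE":
        return MODERATE
    if impact == "LOW":
        return LOW
    # modifier variants
    in_oc = bool(memberships.get("oc", False))
    if scheme.name == "FOUR":
        return OTHER
    if scheme.name == "FIVE":
        return OC if in_oc else NKF
    # EIGHT
    if memberships.get("utr", False):
        return UTR
    if in_oc:
        return OC
    if memberships.get("re", False):
        return RE
    if memberships.get("ncrna", False):
        return NCRNA
    return NKI


def assign_categories(
    variant_ids,
    terms_by_variant: dict[str, set],
    interval_memberships: pd.DataFrame | None = None,
    impact_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Build the full per-variant assignment table.

    Parameters
    ----------
    variant_ids : sequence of str
        All tested variants (post-QC); variants without VEP rows get MODIFIER.
    terms_by_variant : dict
        Consequence term sets collected across VEP rows.
    interval_memberships : DataFrame, optional
        Indexed by variant id with boolean columns ``oc, utr, re, ncrna``.

    Returns
    -------
    DataFrame indexed by variant id with columns impact, oc, utr, re, ncrna,
    cat4, cat5, cat8.
    """
    rows = []
    for vid in variant_ids:
        terms = terms_by_variant.get(vid, set())
        if terms:
            impact = impact_rank(terms, impact_map)
        else:
            impact = "MODIFIER"
        if interval_memberships is not None and vid in interval_memberships.index:
            mem = {c: bool(interval_memberships.loc[vid, c]) for c in INTERVAL_CLASSES}
        else:
            mem = {c: False for c in INTERVAL_CLASSES}
        rows.append(
            dict(
                variant_id=vid,
                impact=impact,
                **mem,
                cat4=classify(impact, mem, FOUR),
                cat5=classify(impact, mem, FIVE),
                cat8=classify(impact, mem, EIGHT),
            )
        )
    return pd.DataFrame(rows).set_index("variant_id")


@dataclass
class CategoryCensus:
    """Genome-wide category counts over all tested variants.

    ``T`` is the total number of tested variants, ``counts[C]`` the number in
    category ``C``; ``frequency`` = counts / T.  These are the denominators of
    the enrichment and weight computations and must cover *all* tested
    variants, not just QTL candidates.
    """

    scheme: CategoryScheme
    counts: pd.Series
    T: int = field(init=False)
    frequency: pd.Series = field(init=False)

    def __post_init__(self):
        self.counts = self.counts.reindex(list(self.scheme.categories), fill_value=0).astype(int)
        self.T = int(self.counts.sum())
        if self.T == 0:
            raise ValueError("census over zero variants")
        self.frequency = self.counts / self.T


def census(category_labels: pd.Series, scheme: str | CategoryScheme) -> CategoryCensus:
    """Count variants per category; labels must belong to the scheme."""
    scheme = get_scheme(scheme)
    labels = pd.Series(category_labels)
    unknown = set(labels.unique()) - set(scheme.categories)
    if unknown:
        raise ValueError(f"labels {sorted(unknown)} not in scheme {scheme.name}")
    return CategoryCensus(scheme, labels.value_counts())


def summarize_consequences(
    terms_by_variant: dict[str, set], impact_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Tally the retained highest-impact consequence term per variant.

    For each variant the single most severe term (first by impact, ties by
    name) is counted; the counts sum to the number of variants.
    """
    impact_map = DEFAULT_IMPACT_MAP if impact_map is None else impact_map
    counter: Counter[str] = Counter()
    for terms in terms_by_variant.values():
        if not terms:
            continue
        best = min(
            sorted(terms),
            key=lambda t: _IMPACT_RANK[impact_map.get(t, "MODIFIER")],
        )
        counter[best] += 1
    df = pd.DataFrame(
        sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["consequence", "count"],
    )
    return df
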