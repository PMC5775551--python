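"""Structural classification of Dscam gene models and isoform-repertoire sizes.

Classification keys on two signals, in order of precedence:

1. **Cassette array structure.** A gene with a tandem 5' variable array is
   sDscamα when each cassette encodes one Ig domain and sDscamβ when each
   encodes two — structure beats domain counts, so α/β genes whose constant
   regions look γ-sized are never misassigned.
2. **Domain architecture.** Without a cassette array: a short constant
   region (≈3 Ig + 3 FNIII + TM) is sDscamγ; the canonical 10 Ig + 6 FNIII
   layout with Ig10 between FNIII4 and FNIII5 is LDscam; the intermediate
   form lacking Ig10 and FNIII3–4 is mDscam.  The mDscam Ig count is
   accepted in a window (8–9 Ig, 3–4 FNIII) because the two published
   readings of the intermediate architecture differ by one N-terminal Ig.

Repertoire sizes follow the promoter/splicing logic of each class: one
isoform per 5' cassette for sDscamα/β (alternative promoters), the product
of cluster sizes for genes diversified by mutually exclusive splicing of
internal exon clusters (the Drosophila Dscam1 mode: 12 × 48 × 33 × 2 =
38,016), and a single isoform otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import prod
from typing import Iterable

import pandas as pd

from .model_io import DscamClass, GeneModel


@dataclass(frozen=True)
class ClassificationRuleSet:
    """Expected domain counts per class, with tolerance windows."""

    ldscam_ig: int = 10
    ldscam_fn3: int = 6
    mdscam_ig_range: tuple[int, int] = (8, 9)
    mdscam_fn3_range: tuple[int, int] = (3, 4)
    sdscam_ig: int = 3
    sdscam_fn3: int = 3
    sdscam_tolerance: int = 1

    def __post_init__(self) -> None:
        if self.sdscam_tolerance < 0:
            raise ValueError("tolerance must be >= 0")


DEFAULT_RULES = ClassificationRuleSet()


def _ig_between_fn3_4_and_5(tokens: tuple[str, ...]) -> bool:
    """True when an IG token sits between the 4th and 5th FN3 token."""
    fn3_positions = [i for i, t in enumerate(tokens) if t == "FN3"]
    if len(fn3_positions) < 5:
        return False
    lo, hi = fn3_positions[3], fn3_positions[4]
    return any(tokens[i] == "IG" for i in range(lo + 1, hi))


def _ig_between_any_fn3(tokens: tuple[str, ...]) -> bool:
    fn3_positions = [i for i, t in enumerate(tokens) if t == "FN3"]
    if len(fn3_positions) < 2:
        return False
    return any(
        tokens[i] == "IG"
        for i in range(fn3_positions[0] + 1, fn3_positions[-1])
    )


def classify_gene(
    gene: GeneModel, rules: ClassificationRuleSet = DEFAULT_RULES
) -> DscamClass:
    """Assign exactly one Dscam class to a gene model.

    Deterministic and total: every syntactically valid gene model gets a
    class, falling back to ``unclassified``.  A cassette array mixing
    1-Ig and 2-Ig units is a malformed annotation and raises.
    """
    if gene.cassette_array:
        ig_counts = {c.encoded_ig_count for c in gene.cassette_array}
        if len(ig_counts) != 1:
            raise ValueError(
                f"{gene.gene_id}: cassette array mixes encoded Ig counts {ig_counts}"
            )
        return (
            DscamClass.SDSCAM_ALPHA
            if ig_counts.pop() == 1
            else DscamClass.SDSCAM_BETA
        )

    arch = gene.architecture
    if arch is None or not arch.domains:
        return DscamClass.UNCLASSIFIED
    ig = arch.count("IG")
    fn3 = arch.count("FN3")
    tol = rules.sdscam_tolerance

    if (
        abs(ig - rules.sdscam_ig) <= tol
        and abs(fn3 - rules.sdscam_fn3) <= tol
        and arch.count("TM") == 1
    ):
        return DscamClass.SDSCAM_GAMMA
    if (
        ig == rules.ldscam_ig
        and fn3 == rules.ldscam_fn3
        and _ig_between_fn3_4_and_5(arch.tokens)
    ):
        return DscamClass.LDSCAM
    if (
        rules.mdscam_ig_range[0] <= ig <= rules.mdscam_ig_range[1]
        and rules.mdscam_fn3_range[0] <= fn3 <= rules.mdscam_fn3_range[1]
        and not _ig_between_any_fn3(arch.tokens)
    ):
        return DscamClass.MDSCAM
    return DscamClass.UNCLASSIFIED


def classify_genes(
    genes: Iterable[GeneModel], rules: ClassificationRuleSet = DEFAULT_RULES
) -> list[GeneModel]:
    """Classify in place; returns the same list for chaining."""
    genes = list(genes)
    for g in genes:
        g.dscam_class = classify_gene(g, rules)
    return genes


def repertoire_size(gene: GeneModel) -> int:
    """Number of distinct isoforms a gene can produce.

    sDscamα/β: one isoform per cassette (alternative promoter choice).
    Mutually-exclusive-exon genes: product of internal cluster sizes.
    Everything else: 1.
    """
    if any(c < 1 for c in gene.internal_clusters):
        raise ValueError(f"{gene.gene_id}: cluster size < 1")
    if gene.dscam_class in (DscamClass.SDSCAM_ALPHA, DscamClass.SDSCAM_BETA):
        return len(gene.cassette_array)
    if gene.internal_clusters:
        return prod(gene.internal_clusters)
    return 1


def variable_exon_count(gene: GeneModel) -> int:
    """Total count of alternative exons: cluster sizes summed, or cassettes."""
    if gene.internal_clusters:
        return sum(gene.internal_clusters)
    return len(gene.cassette_array)


_CLASS_ORDER = [
    DscamClass.LDSCAM,
    DscamClass.MDSCAM,
    DscamClass.SDSCAM_ALPHA,
    DscamClass.SDSCAM_BETA,
    DscamClass.SDSCAM_GAMMA,
    DscamClass.UNCLASSIFIED,
]


def species_repertoire(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-species census: gene counts per class and summed isoform counts.

    One row per species; columns are the per-class gene counts, the total
    gene count, and the total isoform repertoire (sum of per-gene
    repertoire sizes).  An empty input yields a header-only frame.
    """
    rows: dict[str, dict] = {}
    for g in sorted(genes, key=lambda g: (g.species, g.gene_id)):
        row = rows.setdefault(
            g.species,
            {"species": g.species, "total_genes": 0, "total_isoforms": 0}
            | {c.value: 0 for c in _CLASS_ORDER},
        )
        row[g.dscam_class.value] += 1
        row["total_genes"] += 1
        row["total_isoforms"] += repertoire_size(g)
    columns = (
        ["species"] + [c.value for c in _CLASS_ORDER] + ["total_genes", "total_isoforms"]
    )
    return pd.DataFrame(list(rows.values()), columns=columns)
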