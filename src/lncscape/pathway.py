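"""Lignin-vs-flavonoid pathway preference of query genes.

The entry enzymes of the phenylpropanoid pathway (PAL, C4H, 4CL) feed both
lignin and flavonoid biosynthesis. A family member is classified by the GO
annotation of its co-expression partners: flavonoid-preferred if its
partners include flavonoid- but no lignin-related genes, lignin-preferred
for the converse, dual when both appear, none when neither does.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import TomNetwork, coexpression_partners

#: GO terms defining the two pathways (flat id sets; no DAG propagation)
FLAVONOID_TERMS = frozenset(
    {
        "GO:0009812",  # flavonoid metabolic process
        "GO:0009813",  # flavonoid biosynthetic process
        "GO:0009962",  # regulation of flavonoid biosynthetic process
        "GO:0009963",  # positive regulation of flavonoid biosynthetic process
        "GO:0009964",  # negative regulation of flavonoid biosynthetic process
        "GO:1903415",  # flavonoid transport from ER to plant-type vacuole
    }
)
LIGNIN_TERMS = frozenset(
    {
        "GO:0009808",  # lignin metabolic process
        "GO:0009809",  # lignin biosynthetic process
        "GO:0046274",  # lignin catabolic process
        "GO:1901141",  # regulation of lignin biosynthetic process
    }
)


@dataclass(frozen=True)
class PathwayTermSets:
    flavonoid_terms: frozenset = FLAVONOID_TERMS
    lignin_terms: frozenset = LIGNIN_TERMS

    def __post_init__(self):
        if not self.flavonoid_terms or not self.lignin_terms:
            raise ValueError("term sets must be non-empty")
        if set(self.flavonoid_terms) & set(self.lignin_terms):
            raise ValueError("flavonoid and lignin term sets must be disjoint")


LABELS = ("flavonoid_preferred", "lignin_preferred", "dual", "none")


@dataclass(frozen=True)
class PreferenceCall:
    gene_id: str
    n_flavonoid_partners: int
    n_lignin_partners: int
    label: str


def tag_partners(
    gene_id: str,
    tom: TomNetwork,
    go_annotation: dict[str, set[str]],
    term_sets: PathwayTermSets = PathwayTermSets(),
    threshold: float = 0.1,
    coding_genes: set[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Split a gene's TOM > threshold partners into flavonoid- and
    lignin-annotated lists (a partner may land in both). Only coding-gene
    partners are considered when ``coding_genes`` is given."""
    partners = coexpression_partners(tom, gene_id, threshold)
    flav, lig = [], []
    for pid, _w in partners:
        if coding_genes is not None and pid not in coding_genes:
            continue
        gos = go_annotation.get(pid, set())
        if gos & term_sets.flavonoid_terms:
            flav.append(pid)
        if gos & term_sets.lignin_terms:
            lig.append(pid)
    return flav, lig


def classify_preference(tagged: dict[str, tuple[list[str], list[str]]]):
    """Label each gene from its tagged partner lists.

    Returns ``(calls, summary)`` where summary counts each label; labels
    partition the query set.
    """
    calls = []
    summary = {label: 0 for label in LABELS}
    for gene_id in sorted(tagged):
        flav, lig = tagged[gene_id]
        nf, nl = len(flav), len(lig)
        if nf > 0 and nl == 0:
            label = "flavonoid_preferred"
        elif nl > 0 and nf == 0:
            label = "lignin_preferred"
        elif nf > 0 and nl > 0:
            label = "dual"
        else:
            label = "none"
        calls.append(PreferenceCall(gene_id, nf, nl, label))
        summary[label] += 1
    return calls, summary
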