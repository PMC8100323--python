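"""Gene-set integration of divergence outliers with expression calls.

The candidate genes of the study are those differentiated in both
genomic structure (they carry a top-ED SNP) and expression (they are a
DEG), i.e. the intersection of the two gene universes. A user-supplied
heat-responsive gene list can additionally be overlapped with the DEGs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .variant_annot import AnnotatedVariant, location_distribution

__all__ = [
    "GeneSetReport",
    "genes_with_outlier_snps",
    "deg_gene_set",
    "intersect_sets",
    "heat_responsive_overlap",
    "location_distribution_of_candidates",
]


@dataclass(frozen=True)
class GeneSetReport:
    """A named gene set with the filters that produced it."""

    name: str
    members: frozenset[str]
    provenance: tuple[str, ...] = ()

    @property
    def cardinality(self) -> int:
        return len(self.members)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.members):
                fh.write(g + "\n")


def genes_with_outlier_snps(
    annotated_outliers: Sequence[AnnotatedVariant], name: str = "ed_outlier_genes"
) -> GeneSetReport:
    """Unique genes carrying at least one non-intergenic outlier SNP."""
    members = frozenset(
        a.gene_id for a in annotated_outliers
        if a.functional_class != "intergenic" and a.gene_id is not None
    )
    return GeneSetReport(
        name=name, members=members,
        provenance=(f"outlier SNPs annotated to genes (n_snps={len(annotated_outliers)})",),
    )


def deg_gene_set(
    de_results, name: str = "degs", universe: Iterable[str] | None = None
) -> GeneSetReport:
    """Gene set of up/down DE calls from a de_test result frame.

    If a gene-model ``universe`` is given, DEG ids absent from it are
    reported with a warning (they cannot intersect the SNP universe).
    """
    hits = frozenset(de_results.index[de_results["direction"] != "ns"])
    if universe is not None:
        missing = sorted(hits - set(universe))
        if missing:
            warnings.warn(
                f"{len(missing)} DEG id(s) absent from the gene-model universe: "
                + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else "")
            )
    return GeneSetReport(
        name=name, members=hits, provenance=("differential expression calls",)
    )


def intersect_sets(a: GeneSetReport, b: GeneSetReport, name: str | None = None) -> GeneSetReport:
    """Set intersection with provenance recording both parents."""
    return GeneSetReport(
        name=name or f"{a.name}&{b.name}",
        members=a.members & b.members,
        provenance=a.provenance + b.provenance + (f"intersection of {a.name} and {b.name}",),
    )


def heat_responsive_overlap(
    degs: GeneSetReport, reference_list: Iterable[str]
) -> GeneSetReport:
    """DEGs that are also on a user-supplied heat-responsive gene list."""
    ref = frozenset(reference_list)
    if not ref:
        raise ValueError("heat-responsive reference list is empty")
    return GeneSetReport(
        name="heat_responsive_degs",
        members=degs.members & ref,
        provenance=degs.provenance + (f"overlap with heat-responsive list (n={len(ref)})",),
    )


def location_distribution_of_candidates(
    annotated_outliers: Sequence[AnnotatedVariant], candidates: GeneSetReport
) -> dict[str, float]:
    """Functional-class percentages of outlier SNPs in candidate genes."""
    if not candidates.members:
        raise ValueError("candidate gene set is empty")
    restricted = [a for a in annotated_outliers if a.gene_id in candidates.members]
    return location_distribution(restricted)
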