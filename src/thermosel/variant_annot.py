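"""Functional classification of SNPs against gene models.

Each variant is assigned exactly one class — ``synonymous``,
``non_synonymous``, ``exon_noncoding``, ``intron``, ``upstream``,
``downstream`` or ``intergenic`` — and, unless intergenic, one gene.
Upstream/downstream are strand-aware windows anchored at the
transcription start/end; coding variants are classified by translating
the reference and alternate codons.

Coordinates are 1-based inclusive on input (GFF3/VCF convention) and in
the public dataclasses; interval-tree internals are 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .pool_ed import PooledVariant

__all__ = [
    "GeneModel",
    "AnnotatedVariant",
    "GeneIndex",
    "build_interval_index",
    "classify_variant",
    "location_distribution",
    "load_gene_models",
    "load_genome",
    "GENIC_CLASSES",
]

#: Genic classes reported by location_distribution (intergenic is separate).
GENIC_CLASSES = (
    "intron",
    "upstream",
    "downstream",
    "synonymous",
    "non_synonymous",
    "exon_noncoding",
)

# Lower rank wins when a position is explicable by several genes.
_CLASS_RANK = {
    "non_synonymous": 0,
    "synonymous": 0,
    "exon_noncoding": 1,
    "intron": 2,
    "upstream": 3,
    "downstream": 4,
}


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand, exon and CDS structure (1-based inclusive)."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"{self.gene_id}: invalid span {self.start}-{self.end}")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s < self.start or e > self.end:
                raise ValueError(f"{self.gene_id}: exon {s}-{e} outside gene span")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = e
        cds_len = sum(e - s + 1 for s, e in self.cds)
        if self.cds and cds_len % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length {cds_len} not divisible by 3")

    @property
    def tss(self) -> int:
        """Transcription start site (strand-aware)."""
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        """Transcription end site (strand-aware)."""
        return self.end if self.strand == "+" else self.start


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant with its functional class and assigned gene."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    functional_class: str
    gene_id: str | None = None
    distance: int | None = None  # bp to TSS/TES for up/downstream
    ed: float | None = None


class GeneIndex:
    """Interval index over gene features for point and window queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._gene_trees: dict[str, IntervalTree] = {}
        self._feature_trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            gt = self._gene_trees.setdefault(g.chrom, IntervalTree())
            ft = self._feature_trees.setdefault(g.chrom, IntervalTree())
            gt[g.start - 1 : g.end] = g.gene_id
            ft[g.start - 1 : g.end] = ("gene", g.gene_id)
            for s, e in g.exons:
                ft[s - 1 : e] = ("exon", g.gene_id)
            for s, e in g.cds:
                ft[s - 1 : e] = ("CDS", g.gene_id)

    def features_at(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        """All (feature_kind, gene_id) pairs overlapping a 1-based position."""
        tree = self._feature_trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree[pos - 1])

    def genes_near(self, chrom: str, pos: int, pad: int) -> list[GeneModel]:
        """Genes whose span lies within ``pad`` bp of a 1-based position."""
        tree = self._gene_trees.get(chrom)
        if tree is None:
            return []
        hits = tree[max(0, pos - 1 - pad) : pos + pad]
        return [self.genes[iv.data] for iv in hits]


def build_interval_index(genes: Sequence[GeneModel]) -> GeneIndex:
    """Build a queryable interval index over gene models."""
    return GeneIndex(genes)


def _cds_sequence(gene: GeneModel, genome: Mapping[str, str]) -> str:
    """Spliced CDS in transcription order (reverse-complemented for '-')."""
    chrom_seq = genome[gene.chrom]
    parts = [chrom_seq[s - 1 : e] for s, e in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq.upper()


def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """0-based offset of a genomic position within the spliced CDS."""
    offset = 0
    if gene.strand == "+":
        for s, e in gene.cds:
            if s <= pos <= e:
                return offset + (pos - s)
            offset += e - s + 1
    else:
        for s, e in reversed(gene.cds):
            if s <= pos <= e:
                return offset + (e - pos)
            offset += e - s + 1
    return None


def _coding_effect(
    gene: GeneModel, pos: int, ref: str, alt: str, genome: Mapping[str, str]
) -> str:
    """'synonymous' or 'non_synonymous' for a CDS substitution."""
    cds_seq = _cds_sequence(gene, genome)
    off = _cds_offset(gene, pos)
    assert off is not None
    if gene.strand == "-":
        ref = str(Seq(ref).reverse_complement())
        alt = str(Seq(alt).reverse_complement())
    codon_start = (off // 3) * 3
    within = off - codon_start
    codon = cds_seq[codon_start : codon_start + 3]
    if codon[within] != ref.upper():
        raise ValueError(
            f"{gene.gene_id}: CDS base at offset {off} is {codon[within]}, expected {ref}"
        )
    alt_codon = codon[:within] + alt.upper() + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return "synonymous" if aa_ref == aa_alt else "non_synonymous"


def _classify_against_gene(
    gene: GeneModel,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genome: Mapping[str, str],
    upstream_window: int,
    downstream_window: int,
) -> tuple[str, int] | None:
    """(class, distance) of a position relative to one gene, or None."""
    if gene.start <= pos <= gene.end:
        in_cds = any(s <= pos <= e for s, e in gene.cds)
        if in_cds:
            # non_synonymous wins if any alternate allele changes the protein
            effects = {_coding_effect(gene, pos, ref, a, genome) for a in alts}
            return ("non_synonymous" if "non_synonymous" in effects else "synonymous", 0)
        if any(s <= pos <= e for s, e in gene.exons):
            return ("exon_noncoding", 0)
        return ("intron", 0)
    # flanks, strand-aware: upstream is 5' of the TSS, downstream 3' of the TES
    if gene.strand == "+":
        if pos < gene.start and gene.start - pos <= upstream_window:
            return ("upstream", gene.start - pos)
        if pos > gene.end and pos - gene.end <= downstream_window:
            return ("downstream", pos - gene.end)
    else:
        if pos > gene.end and pos - gene.end <= upstream_window:
            return ("upstream", pos - gene.end)
        if pos < gene.start and gene.start - pos <= downstream_window:
            return ("downstream", gene.start - pos)
    return None


def classify_variant(
    variant: PooledVariant,
    index: GeneIndex,
    genome: Mapping[str, str],
    upstream_window: int = 3000,
    downstream_window: int = 3000,
    ed: float | None = None,
) -> AnnotatedVariant:
    """Assign exactly one functional class and gene to a variant.

    Precedence when several genes could claim the position:
    CDS (non)synonymous > non-coding exon > intron > upstream >
    downstream > intergenic; among genes offering the same class, the
    one whose TSS is nearest wins.

    Raises ``ValueError`` if the variant's reference allele disagrees
    with the genome sequence at its position.
    """
    chrom_seq = genome[variant.chrom]
    if not 1 <= variant.pos <= len(chrom_seq):
        raise ValueError(f"{variant.variant_id}: position outside genome bounds")
    genome_base = chrom_seq[variant.pos - 1].upper()
    if genome_base != variant.ref.upper():
        raise ValueError(
            f"{variant.variant_id}: reference allele {variant.ref} does not match "
            f"genome base {genome_base}"
        )
    pad = max(upstream_window, downstream_window)
    best: tuple[int, int, str, str, int] | None = None
    for gene in index.genes_near(variant.chrom, variant.pos, pad):
        hit = _classify_against_gene(
            gene, variant.pos, variant.ref, variant.alts, genome,
            upstream_window, downstream_window,
        )
        if hit is None:
            continue
        klass, dist = hit
        key = (_CLASS_RANK[klass], abs(variant.pos - gene.tss), gene.gene_id)
        if best is None or key < (best[0], best[1], best[3]):
            best = (key[0], key[1], klass, gene.gene_id, dist)
    if best is None:
        return AnnotatedVariant(
            variant_id=variant.variant_id, chrom=variant.chrom, pos=variant.pos,
            ref=variant.ref, alt=variant.alts[0] if variant.alts else ".",
            functional_class="intergenic", ed=ed,
        )
    _, _, klass, gene_id, dist = best
    return AnnotatedVariant(
        variant_id=variant.variant_id, chrom=variant.chrom, pos=variant.pos,
        ref=variant.ref, alt=variant.alts[0] if variant.alts else ".",
        functional_class=klass, gene_id=gene_id,
        distance=dist if klass in ("upstream", "downstream") else None, ed=ed,
    )


def location_distribution(annotated: Sequence[AnnotatedVariant]) -> dict[str, float]:
    """Percentage of genic variants per functional class.

    Intergenic variants are excluded (report them separately); the
    returned percentages sum to 100 over the genic classes.
    """
    genic = [a for a in annotated if a.functional_class != "intergenic"]
    if not genic:
        raise ValueError("no genic variants to summarize")
    out = {c: 0.0 for c in GENIC_CLASSES}
    for a in genic:
        out[a.functional_class] += 1
    return {c: 100.0 * n / len(genic) for c, n in out.items()}


def load_genome(fasta_path: str) -> dict[str, str]:
    """Read a FASTA into a plain chrom -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(fasta_path, "fasta")}


def load_gene_models(gff3_path: str) -> list[GeneModel]:
    """Read gene models from a GFF3 file (gene/exon/CDS features).

    Multi-isoform genes are collapsed: exons are unioned and the CDS of
    the longest coding isoform is used for synonymous/non-synonymous
    calls.
    """
    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exon_ivs = sorted(
            {(f.start, f.end) for f in db.children(g, featuretype="exon")}
        )
        exon_ivs = _merge_intervals(exon_ivs)
        mrnas = list(db.children(g, featuretype="mRNA"))
        cds_ivs: list[tuple[int, int]] = []
        if mrnas:
            best_len = -1
            for m in mrnas:
                ivs = sorted((f.start, f.end) for f in db.children(m, featuretype="CDS"))
                length = sum(e - s + 1 for s, e in ivs)
                if length > best_len:
                    best_len, cds_ivs = length, ivs
        else:
            cds_ivs = sorted({(f.start, f.end) for f in db.children(g, featuretype="CDS")})
        genes.append(
            GeneModel(
                gene_id=g.id, chrom=g.seqid, strand=g.strand,
                start=g.start, end=g.end,
                exons=tuple(exon_ivs), cds=tuple(cds_ivs),
            )
        )
    if not genes:
        warnings.warn(f"no gene features found in {gff3_path}")
    return genes


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged
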