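"""SNP functional classification against gene models.

The heavy check is oracle equivalence: an independent per-base labeller
that linearly scans every gene for every position must agree with the
interval-index classifier over whole synthetic chromosomes, on both
strands.
"""

import numpy as np
import pytest
from Bio.Seq import Seq

from thermosel.pool_ed import PooledVariant
from thermosel.synthetic_data import SimulationConfig, gen_genome_and_genes
from thermosel.variant_annot import (
    AnnotatedVariant,
    GeneModel,
    build_interval_index,
    classify_variant,
    location_distribution,
)


def _variant(chrom, pos, ref, alt):
    return PooledVariant(
        chrom=chrom, pos=pos, ref=ref, alts=(alt,),
        depths_pool1=(10, 10), depths_pool2=(10, 10),
    )


def _brute_force_class(genes, chrom, pos, up_w, down_w):
    """Independent per-position labeller: linear scan, explicit rules."""
    best = None  # (rank, tss_dist, gene_id, class)
    rank = {"cds": 0, "exon_noncoding": 1, "intron": 2, "upstream": 3, "downstream": 4}
    for g in genes:
        if g.chrom != chrom:
            continue
        klass = None
        if g.start <= pos <= g.end:
            if any(s <= pos <= e for s, e in g.cds):
                klass = "cds"
            elif any(s <= pos <= e for s, e in g.exons):
                klass = "exon_noncoding"
            else:
                klass = "intron"
        else:
            tss = g.start if g.strand == "+" else g.end
            tes = g.end if g.strand == "+" else g.start
            before_tss = pos < tss if g.strand == "+" else pos > tss
            if before_tss and abs(tss - pos) <= up_w:
                klass = "upstream"
            elif (not before_tss) and 0 < abs(pos - tes) <= down_w:
                klass = "downstream"
        if klass is None:
            continue
        tss = g.start if g.strand == "+" else g.end
        key = (rank[klass], abs(pos - tss), g.gene_id)
        if best is None or key < best[:3]:
            best = (*key, klass)
    return ("intergenic", None) if best is None else (best[3], best[2])


@pytest.fixture(scope="module")
def plus_gene_setup():
    # hand-built gene on chr1:+: exon1 5001-5090, intron, exon2 5201-5320
    # CDS = both exons (90 + 120 = 210 bp, divisible by 3)
    cds_seq = "ATG" + "GCT" * 68 + "TAA"  # Met, 68x Ala, stop = 210 bp
    genome_seq = ["A"] * 10_000
    genome_seq[5000:5090] = list(cds_seq[:90])
    genome_seq[5200:5320] = list(cds_seq[90:])
    genome = {"chr1": "".join(genome_seq)}
    gene = GeneModel(
        gene_id="G1", chrom="chr1", strand="+", start=5001, end=5320,
        exons=((5001, 5090), (5201, 5320)), cds=((5001, 5090), (5201, 5320)),
    )
    return genome, gene, build_interval_index([gene])


class TestClassifyAgainstHandBuiltGene:
    def test_upstream_snp_2150bp_before_tss(self, plus_gene_setup):
        """A SNP ~2.1 kb 5' of a plus-strand TSS is upstream at window 3000."""
        genome, gene, index = plus_gene_setup
        pos = gene.start - 2150
        a = classify_variant(_variant("chr1", pos, "A", "G"), index, genome)
        assert a.functional_class == "upstream"
        assert a.gene_id == "G1" and a.distance == 2150

    def test_beyond_window_is_intergenic(self, plus_gene_setup):
        genome, gene, index = plus_gene_setup
        a = classify_variant(
            _variant("chr1", gene.start - 3500, "A", "G"), index, genome
        )
        assert a.functional_class == "intergenic" and a.gene_id is None

    def test_between_exons_is_intron(self, plus_gene_setup):
        genome, _, index = plus_gene_setup
        a = classify_variant(_variant("chr1", 5150, "A", "G"), index, genome)
        assert a.functional_class == "intron" and a.gene_id == "G1"

    def test_synonymous_vs_nonsynonymous_codon(self, plus_gene_setup):
        """GCT->GCC keeps Ala (synonymous); GCT->GTT gives Val."""
        genome, gene, index = plus_gene_setup
        # first Ala codon: CDS offsets 3,4,5 -> genomic 1004-1006; third base
        pos_third = 5006
        syn = classify_variant(_variant("chr1", pos_third, "T", "C"), index, genome)
        assert syn.functional_class == "synonymous"
        pos_second = 5005
        non = classify_variant(_variant("chr1", pos_second, "C", "T"), index, genome)
        assert non.functional_class == "non_synonymous"

    def test_reference_mismatch_is_an_error(self, plus_gene_setup):
        genome, _, index = plus_gene_setup
        with pytest.raises(ValueError, match="does not match"):
            classify_variant(_variant("chr1", 50, "C", "T"), index, genome)

    def test_downstream_of_plus_strand_gene(self, plus_gene_setup):
        genome, gene, index = plus_gene_setup
        a = classify_variant(_variant("chr1", gene.end + 500, "A", "G"), index, genome)
        assert a.functional_class == "downstream" and a.distance == 500


class TestIndex:
    def test_empty_gene_list_returns_nothing(self):
        index = build_interval_index([])
        assert index.features_at("chr1", 100) == []
        assert index.genes_near("chr1", 100, 5000) == []

    def test_point_inside_exon_returns_exon(self, plus_gene_setup):
        _, _, index = plus_gene_setup
        kinds = {k for k, _ in index.features_at("chr1", 5050)}
        assert "exon" in kinds

    def test_index_equals_linear_scan(self, small_genome, rng):
        """Feature point-queries match a brute-force scan over all features."""
        genome, genes = small_genome
        index = build_interval_index(genes)
        features = []
        for g in genes:
            features.append(("gene", g.gene_id, g.start, g.end, g.chrom))
            for s, e in g.exons:
                features.append(("exon", g.gene_id, s, e, g.chrom))
            for s, e in g.cds:
                features.append(("CDS", g.gene_id, s, e, g.chrom))
        for _ in range(1000):
            chrom = f"chr{rng.integers(1, 3)}"
            pos = int(rng.integers(1, len(genome[chrom]) + 1))
            expected = sorted(
                (k, gid) for k, gid, s, e, c in features if c == chrom and s <= pos <= e
            )
            assert index.features_at(chrom, pos) == expected


class TestOracleEquivalence:
    def test_classification_matches_per_base_oracle(self, rng):
        """Index classifier agrees with an independent per-base labeller
        over a whole synthetic chromosome, minus strand included."""
        cfg = SimulationConfig(seed=5, n_chromosomes=1, chrom_length=100_000, n_genes=8)
        genome, genes = gen_genome_and_genes(cfg)
        assert {g.strand for g in genes} == {"+", "-"}
        index = build_interval_index(genes)
        positions = rng.integers(1, 100_001, size=3000)
        for pos in positions:
            pos = int(pos)
            ref = genome["chr1"][pos - 1]
            alt = "A" if ref != "A" else "G"
            got = classify_variant(_variant("chr1", pos, ref, alt), index, genome)
            exp_class, exp_gene = _brute_force_class(genes, "chr1", pos, 3000, 3000)
            got_class = (
                "cds" if got.functional_class in ("synonymous", "non_synonymous")
                else got.functional_class
            )
            assert (got_class, got.gene_id) == (exp_class, exp_gene), f"pos {pos}"

    def test_strand_symmetry(self):
        """Reverse-complementing the genome and flipping strands/coordinates
        leaves every classification unchanged."""
        cfg = SimulationConfig(seed=9, n_chromosomes=1, chrom_length=60_000, n_genes=5)
        genome, genes = gen_genome_and_genes(cfg)
        index = build_interval_index(genes)
        L = len(genome["chr1"])
        flipped_genome = {"chr1": str(Seq(genome["chr1"]).reverse_complement())}
        flipped_genes = [
            GeneModel(
                gene_id=g.gene_id, chrom="chr1",
                strand="-" if g.strand == "+" else "+",
                start=L - g.end + 1, end=L - g.start + 1,
                exons=tuple(sorted((L - e + 1, L - s + 1) for s, e in g.exons)),
                cds=tuple(sorted((L - e + 1, L - s + 1) for s, e in g.cds)),
            )
            for g in genes
        ]
        flipped_index = build_interval_index(flipped_genes)
        rng = np.random.default_rng(3)
        for pos in rng.integers(1, L + 1, size=800):
            pos = int(pos)
            ref = genome["chr1"][pos - 1]
            alt = "A" if ref != "A" else "G"
            a = classify_variant(_variant("chr1", pos, ref, alt), index, genome)
            fpos = L - pos + 1
            fref = str(Seq(ref).reverse_complement())
            falt = str(Seq(alt).reverse_complement())
            b = classify_variant(
                _variant("chr1", fpos, fref, falt), flipped_index, flipped_genome
            )
            assert a.functional_class == b.functional_class, f"pos {pos}"
            assert a.gene_id == b.gene_id and a.distance == b.distance


class TestLocationDistribution:
    @staticmethod
    def _annot(klass, gene="G1", i=0):
        return AnnotatedVariant(
            variant_id=f"chr1:{i}", chrom="chr1", pos=i + 1, ref="A", alt="T",
            functional_class=klass, gene_id=None if klass == "intergenic" else gene,
        )

    def test_all_intronic(self):
        dist = location_distribution([self._annot("intron", i=i) for i in range(10)])
        assert dist["intron"] == 100.0

    def test_even_split(self):
        ann = [self._annot("intron", i=i) for i in range(5)] + [
            self._annot("upstream", i=i + 5) for i in range(5)
        ]
        dist = location_distribution(ann)
        assert dist["intron"] == dist["upstream"] == 50.0

    def test_matches_hand_tally_and_ignores_intergenic(self):
        classes = (
            ["intron"] * 9 + ["upstream"] * 4 + ["downstream"] * 3
            + ["synonymous"] * 2 + ["non_synonymous"] * 2 + ["intergenic"] * 5
        )
        ann = [self._annot(c, i=i) for i, c in enumerate(classes)]
        dist = location_distribution(ann)
        assert dist["intron"] == pytest.approx(100 * 9 / 20)
        assert dist["upstream"] == pytest.approx(100 * 4 / 20)
        assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            location_distribution([])
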