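#!/usr/bin/env python
"""Generate the synthetic study dataset.

Emulates the experiment's data layers under their study conditions: a
two-chromosome genome with 40 gene models, 2000 pooled-seq SNPs at 82x
per pool (5% under divergent selection, allele-frequency shift 0.5),
negative-binomial RNA-seq counts for 3 selected vs 3 control replicates
(10% DE at 4-fold), an adult qPCR heat-shock time course with genotype
effects, closed-chamber O2 traces (0.0012 vs 0.0006 mg/mL/h), and a
field survival trial (p = 0.73 vs 0.62, 3 cages x 100).  Writes all
inputs plus truth tables to results/data/.
"""

import sys
from pathlib import Path

from thermosel import synthetic_data as sd
from thermosel.synthetic_data import SimulationConfig

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    genome, genes = sd.gen_genome_and_genes(cfg)
    variants, snp_truth = sd.gen_pool_variants(cfg, genes, genome=genome)
    counts, groups, de_truth = sd.gen_expression(
        cfg, gene_ids=[g.gene_id for g in genes]
    )
    qpcr = sd.gen_qpcr(cfg, genotype_effects={"CC": -1.5, "CT": -0.5, "TT": 0.0})
    traces = sd.gen_respirometry_cohort(cfg)
    survival = sd.gen_survival(cfg)
    reads = sd.gen_reads(cfg)

    sd.write_fasta(genome, OUT / "genome.fa")
    sd.write_gff3(genes, OUT / "genes.gff3")
    sd.write_vcf(variants, OUT / "variants.vcf",
                 contig_lengths={c: len(s) for c, s in genome.items()})
    snp_truth.selected_frame().to_csv(OUT / "truth_snps.tsv", sep="\t", index=False)
    counts.to_csv(OUT / "counts.tsv", sep="\t")
    groups.rename_axis("sample").reset_index().to_csv(
        OUT / "groups.tsv", sep="\t", index=False
    )
    de_truth.de_frame().to_csv(OUT / "truth_de.tsv", sep="\t", index=False)
    qpcr.to_csv(OUT / "qpcr.tsv", sep="\t", index=False)
    traces.to_csv(OUT / "respirometry.tsv", sep="\t", index=False)
    survival.to_csv(OUT / "survival.tsv", sep="\t", index=False)
    sd.write_fastq(reads, OUT / "reads.fastq")

    print(f"seed {SEED}: wrote {len(genes)} genes, {len(variants)} SNPs "
          f"({len(snp_truth.selected_snp_ids)} under selection), "
          f"{counts.shape[0]}x{counts.shape[1]} count matrix "
          f"({len(de_truth.de_gene_ids)} true DE genes), "
          f"{len(qpcr)} qPCR rows, {traces['subject'].nunique()} O2 traces, "
          f"{len(reads)} reads -> {OUT}")


if __name__ == "__main__":
    main()
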