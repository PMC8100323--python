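#!/usr/bin/env python
"""Functional annotation of the ED-outlier SNPs.

Classifies each outlier against the gene models (strand-aware 3 kb
up/downstream windows, codon-level synonymous calls) and prints the
genic-location distribution, the synthetic analogue of the published
intron/upstream/downstream/synonymous/non-synonymous breakdown.
"""

from pathlib import Path

import pandas as pd

from thermosel import pool_ed, variant_annot

DATA = Path("results/data")
OUT = Path("results/annot")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = variant_annot.load_genome(str(DATA / "genome.fa"))
    genes = variant_annot.load_gene_models(str(DATA / "genes.gff3"))
    index = variant_annot.build_interval_index(genes)
    variants = {v.variant_id: v for v in pool_ed.read_pooled_vcf(str(DATA / "variants.vcf"))}

    scan = pd.read_csv("results/ed/ed_scan.tsv", sep="\t")
    outliers = scan[scan["outlier"]]
    annotated = []
    for row in outliers.itertuples():
        vid = f"{row.chrom}:{row.pos}"
        annotated.append(
            variant_annot.classify_variant(variants[vid], index, genome, ed=row.ed)
        )
    pd.DataFrame(
        [(a.variant_id, a.ed, a.functional_class, a.gene_id or "", a.distance)
         for a in annotated],
        columns=["snp_id", "ed", "class", "gene_id", "distance"],
    ).to_csv(OUT / "annotated_outliers.tsv", sep="\t", index=False)

    genic = [a for a in annotated if a.functional_class != "intergenic"]
    print(f"{len(annotated)} outlier SNPs annotated; {len(genic)} genic, "
          f"{len(annotated) - len(genic)} intergenic")
    if genic:
        dist = variant_annot.location_distribution(annotated)
        print("genic location distribution (%):",
              {k: round(v, 1) for k, v in dist.items() if v > 0})


if __name__ == "__main__":
    main()
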