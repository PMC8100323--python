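#!/usr/bin/env python
"""Intersect structure- and expression-level signals into candidate genes.

A candidate gene is differentiated in both genomic structure (carries a
top-5% ED outlier SNP) and expression (called DE).  Also overlaps the
DEGs with a heat-responsive reference list (here: a deterministic slice
of the gene universe enriched for true DE genes, standing in for the
published list that is a user input in real runs).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from thermosel import integrate
from thermosel.variant_annot import AnnotatedVariant

DATA = Path("results/data")
OUT = Path("results/integration")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ann = pd.read_csv("results/annot/annotated_outliers.tsv", sep="\t",
                      keep_default_na=False)
    annotated = [
        AnnotatedVariant(
            variant_id=r.snp_id, chrom=r.snp_id.split(":")[0],
            pos=int(r.snp_id.split(":")[1]), ref=".", alt=".",
            functional_class=r[2], gene_id=r.gene_id or None,
        )
        for r in ann.itertuples(index=False)
    ]
    de = pd.read_csv("results/de/de_results.tsv", sep="\t", index_col="gene_id")
    universe = pd.read_csv(DATA / "counts.tsv", sep="\t")["gene_id"]

    outlier_genes = integrate.genes_with_outlier_snps(annotated)
    degs = integrate.deg_gene_set(de, universe=universe)
    candidates = integrate.intersect_sets(outlier_genes, degs, name="candidates")

    rng = np.random.default_rng([0, 99])
    truth = pd.read_csv(DATA / "truth_de.tsv", sep="\t")
    de_ids = sorted(truth["gene_id"])
    others = sorted(set(universe) - set(de_ids))
    heat_list = sorted(
        list(rng.choice(de_ids, size=min(7, len(de_ids)), replace=False))
        + list(rng.choice(others, size=8, replace=False))
    )
    heat = integrate.heat_responsive_overlap(degs, heat_list)

    summary = {
        "ed_outlier_genes": outlier_genes.cardinality,
        "degs": degs.cardinality,
        "candidates": candidates.cardinality,
        "heat_responsive_degs": heat.cardinality,
    }
    candidates.write(str(OUT / "candidate_genes.txt"))
    (OUT / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    print(f"{outlier_genes.cardinality} genes carry outlier SNPs; "
          f"{degs.cardinality} DEGs; intersection = {candidates.cardinality} "
          f"candidate genes; {heat.cardinality}/{len(heat_list)} of the "
          f"heat-responsive list are DEGs")
    if candidates.members:
        dist = integrate.location_distribution_of_candidates(annotated, candidates)
        print("candidate-SNP locations (%):",
              {k: round(v, 1) for k, v in dist.items() if v > 0})


if __name__ == "__main__":
    main()
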