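#!/usr/bin/env python
"""Read QC and differential expression between selected and control larvae.

Applies the read-level filters (adaptor, N > 10%, Phred <= 10 at > 50%
of bases), then calls per-gene differential expression from the count
matrix (median-of-ratios normalisation, moderated t on log2 counts, BH
at FDR 0.05 with |log2FC| >= 1) and scores the calls against the
generator's truth table.
"""

from pathlib import Path

import pandas as pd

from thermosel import diff_expr

DATA = Path("results/data")
OUT = Path("results/de")
ADAPTOR = "AGATCGGAAGAGC"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tally = diff_expr.filter_fastq(
        str(DATA / "reads.fastq"), str(OUT / "reads.clean.fastq"), adaptor=ADAPTOR
    )
    print(f"QC: kept {tally.kept}/{tally.total} reads "
          f"(adaptor {tally.adaptor}, high-N {tally.high_n}, "
          f"low-quality {tally.low_quality})")

    counts = pd.read_csv(DATA / "counts.tsv", sep="\t", index_col="gene_id")
    groups = pd.read_csv(DATA / "groups.tsv", sep="\t", index_col="sample")["group"]
    res = diff_expr.de_test(counts, groups, alpha=0.05, lfc_min=1.0)
    res.rename_axis("gene_id").reset_index().to_csv(
        OUT / "de_results.tsv", sep="\t", index=False
    )
    n_up, n_down = diff_expr.up_down_counts(res)

    truth = pd.read_csv(DATA / "truth_de.tsv", sep="\t")
    true_ids = set(truth["gene_id"])
    called = set(res.index[res["direction"] != "ns"])
    tp = len(called & true_ids)
    print(f"DE: {n_up} up + {n_down} down of {len(res)} genes; "
          f"{tp}/{len(true_ids)} true DE genes recovered, "
          f"{len(called) - tp} false calls")


if __name__ == "__main__":
    main()
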