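"""Bundled reference tables from the oyster thermotolerance experiment.

Two small published tables travel with the package: the eight
top-divergence SNPs in differentially expressed HSP genes (with their
ED values and genic locations), and the genotype classes observed for
the two SNPs that were successfully genotyped in adults.  They serve as
real-data fixtures for the retention and genotyping summaries.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["hsp_snp_table", "validated_genotype_table"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__name__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def hsp_snp_table() -> pd.DataFrame:
    """Eight candidate HSP-gene SNPs with ED values and genic locations."""
    return _read("hsp_snps.tsv")


def validated_genotype_table() -> pd.DataFrame:
    """Genotype classes of the two SNPs validated in 1-year-old oysters."""
    return _read("validated_genotypes.tsv")
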