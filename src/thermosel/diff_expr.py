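"""Read-level QC and differential expression between two groups.

QC applies three removal rules to raw reads: adaptor contamination,
more than 10% ambiguous (N) bases, and Phred <= 10 at more than 50% of
bases.  The boundaries are strict inequalities: a read at exactly 10% N
or exactly 50% low-quality bases is kept.

Differential expression uses median-of-ratios size factors, a per-gene
t-test on log2(normalised count + 1), and Benjamini-Hochberg control of
the false discovery rate.  With the study's three replicates per group
a per-gene variance estimate has so few degrees of freedom that no gene
can clear an FDR threshold, so the default test moderates the per-gene
variances with an empirical-Bayes squeeze toward a prior fitted across
genes (the moderated t of microarray/RNA-seq practice); a plain Welch
t-test is available for larger designs.  A gene is called up/down only
if its adjusted p-value clears ``alpha`` and its |log2 fold change|
clears ``lfc_min``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ReadRecord",
    "QCTally",
    "filter_reads",
    "filter_fastq",
    "size_factors",
    "de_test",
    "up_down_counts",
]

N_FRAC_MAX = 0.10  # remove when N fraction strictly exceeds this
LOWQ_PHRED = 10  # a base is "low quality" when Phred <= this
LOWQ_FRAC_MAX = 0.50  # remove when low-quality fraction strictly exceeds this


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    name: str
    sequence: str
    qualities: tuple[int, ...]
    adaptor_match: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.name}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )


@dataclass
class QCTally:
    """Per-reason removal counts from a QC pass."""

    kept: int = 0
    adaptor: int = 0
    high_n: int = 0
    low_quality: int = 0

    @property
    def removed(self) -> int:
        return self.adaptor + self.high_n + self.low_quality

    @property
    def total(self) -> int:
        return self.kept + self.removed


def _qc_fate(read: ReadRecord, adaptor: str | None) -> str:
    if read.adaptor_match or (adaptor and adaptor in read.sequence):
        return "adaptor"
    seq = read.sequence.upper()
    if seq.count("N") > N_FRAC_MAX * len(seq):
        return "high_n"
    n_lowq = sum(q <= LOWQ_PHRED for q in read.qualities)
    if n_lowq > LOWQ_FRAC_MAX * len(read.qualities):
        return "low_quality"
    return "kept"


def filter_reads(
    reads: Iterable[ReadRecord], tally: QCTally, adaptor: str | None = None
) -> Iterator[ReadRecord]:
    """Yield reads passing all QC rules; count removals by reason.

    Rules, applied in order: adaptor (caller-set flag or literal
    substring of ``adaptor``), N fraction > 10%, fraction of bases with
    Phred <= 10 over 50%.  All boundaries are strict, so reads exactly
    at 10% N or 50% low-quality bases pass.
    """
    for read in reads:
        fate = _qc_fate(read, adaptor)
        setattr(tally, fate, getattr(tally, fate) + 1)
        if fate == "kept":
            yield read


def filter_fastq(
    in_path: str, out_path: str, adaptor: str | None = None
) -> QCTally:
    """QC a FASTQ file (Phred+33) to a new FASTQ; returns the tally."""
    tally = QCTally()
    with open(out_path, "w") as out:
        for rec in SeqIO.parse(in_path, "fastq"):
            read = ReadRecord(
                name=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
            )
            fate = _qc_fate(read, adaptor)
            setattr(tally, fate, getattr(tally, fate) + 1)
            if fate == "kept":
                SeqIO.write(rec, out, "fastq")
    return tally


def size_factors(matrix: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factor per sample.

    For each gene expressed in every sample, form the ratio of its count
    in sample *s* to its geometric mean across samples; the sample's
    factor is the median ratio.  Requires at least one gene with nonzero
    counts in all samples.
    """
    counts = matrix.to_numpy(dtype=float)
    expressed = (counts > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene has nonzero counts in every sample")
    sub = counts[expressed]
    log_gm = np.mean(np.log(sub), axis=1, keepdims=True)
    ratios = sub / np.exp(log_gm)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=matrix.columns, name="size_factor")


def _invert_trigamma(target: float) -> float:
    """Solve trigamma(x) = target for x > 0 (Newton, monotone decreasing)."""
    x = 0.5 + 1.0 / target  # asymptotic start: trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(50):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / target) / special.polygamma(2, x)
        x = max(x - step, 1e-8)
        if abs(tri - target) < 1e-10 * target:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene sample variances.

    Fits a scaled-F prior to the observed variances by matching the
    moments of log(s^2) (digamma/trigamma identities), then returns the
    posterior variances ``(d0*s0^2 + df*s^2) / (d0 + df)`` and the prior
    degrees of freedom ``d0`` (``inf`` when the observed spread is no
    wider than chi-square sampling noise alone).
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        return s2, 0.0
    z = np.log(positive)
    z_var = float(np.var(z, ddof=1))
    excess = z_var - float(special.polygamma(1, df / 2.0))
    e_bias = float(special.digamma(df / 2.0) - np.log(df / 2.0))
    if excess <= 0:
        d0 = np.inf
        s02 = float(np.exp(np.mean(z) - e_bias))
        return np.full_like(s2, s02), d0
    d0 = 2.0 * _invert_trigamma(excess)
    s02 = float(
        np.exp(np.mean(z) - e_bias + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    )
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0


def de_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    group_a: str = "selected",
    group_b: str = "control",
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-gene differential expression of ``group_a`` vs ``group_b``.

    Counts are normalised by median-of-ratios factors; the log2 fold
    change is computed from group means of normalised counts with a 0.5
    pseudocount; the per-gene test is on log2(normalised + 1) — a
    moderated t with empirical-Bayes variance shrinkage by default
    (essential at 2-3 replicates per group), or a plain Welch t with
    ``method="welch"``; adjustment is Benjamini-Hochberg.  Returns a
    frame indexed by gene with columns log2fc, pvalue, padj and
    direction (up/down/ns).
    """
    groups = groups.reindex(matrix.columns)
    a_cols = groups.index[groups == group_a]
    b_cols = groups.index[groups == group_b]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"need >=2 replicates per group, got {len(a_cols)} vs {len(b_cols)}"
        )
    factors = size_factors(matrix)
    norm = matrix / factors
    mean_a = norm[a_cols].mean(axis=1)
    mean_b = norm[b_cols].mean(axis=1)
    log2fc = np.log2(mean_a + 0.5) - np.log2(mean_b + 0.5)

    log_norm = np.log2(norm + 1.0)
    xa = log_norm[a_cols].to_numpy()
    xb = log_norm[b_cols].to_numpy()
    if method == "welch":
        _, pval = stats.ttest_ind(xa, xb, axis=1, equal_var=False)
        pval = np.where(np.isnan(pval), 1.0, pval)  # zero-variance genes: no call
    elif method == "moderated":
        na, nb = xa.shape[1], xb.shape[1]
        df_resid = na + nb - 2
        diff = xa.mean(axis=1) - xb.mean(axis=1)
        s2 = (
            np.sum((xa - xa.mean(axis=1, keepdims=True)) ** 2, axis=1)
            + np.sum((xb - xb.mean(axis=1, keepdims=True)) ** 2, axis=1)
        ) / df_resid
        s2_post, d0 = squeeze_variances(s2, df_resid)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = diff / se
        df_total = df_resid + d0
        if np.isinf(df_total):
            pval = 2.0 * stats.norm.sf(np.abs(tstat))
        else:
            pval = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        pval = np.where(np.isnan(pval), 1.0, pval)
    else:
        raise ValueError(f"unknown method {method!r}")
    _, padj, _, _ = multipletests(pval, method="fdr_bh")

    direction = np.where(
        (padj < alpha) & (np.abs(log2fc) >= lfc_min),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pval, "padj": padj, "direction": direction},
        index=matrix.index,
    )


def up_down_counts(results: pd.DataFrame) -> tuple[int, int]:
    """(number of up-regulated, number of down-regulated) calls."""
    return (
        int((results["direction"] == "up").sum()),
        int((results["direction"] == "down").sum()),
    )
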