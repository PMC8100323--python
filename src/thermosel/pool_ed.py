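"""Per-SNP Euclidean-distance (ED) divergence between two DNA pools.

In a pooled-sequencing design, DNA from many individuals of each
population is sequenced as a single library, so allele frequencies are
estimated from per-allele read depths rather than genotypes.  The ED
statistic for one site is the Euclidean norm of the difference between
the two pools' allele-frequency vectors; for a biallelic site this
reduces to ``sqrt(2) * |f1 - f2|`` where f is the alternate-allele
frequency.  Sites with ED below a screening threshold (default 0.3) are
discarded, and the top fraction of the remaining sites by ED are treated
as candidate selection outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "PooledVariant",
    "EDRecord",
    "allele_frequencies",
    "compute_ed",
    "ed_scan",
    "ed_table",
    "top_percentile",
    "ed_class_histogram",
    "read_pooled_vcf",
    "ED_MAX",
]

#: Maximal attainable ED for frequency vectors (two fixed, opposite alleles).
ED_MAX = math.sqrt(2.0)

#: Default screening threshold: sites with ED below this are removed.
DEFAULT_ED_MIN = 0.3

#: Histogram bins used for the retained-ED class distribution. Left-closed,
#: right-open, except the last bin which is closed at sqrt(2).
ED_CLASS_BINS = (
    ("0.3-0.4", 0.3, 0.4),
    ("0.4-0.5", 0.4, 0.5),
    ("0.5-0.6", 0.5, 0.6),
    ("0.6-0.7", 0.6, 0.7),
    ("0.7-0.8", 0.7, 0.8),
    (">0.8", 0.8, ED_MAX + 1e-9),
)


@dataclass(frozen=True)
class PooledVariant:
    """One variant site with per-pool allele read depths.

    Depth vectors list the reference allele first, then each alternate
    allele in order, and must have the same length (``1 + len(alts)``)
    in both pools.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    depths_pool1: tuple[int, ...]
    depths_pool2: tuple[int, ...]

    def __post_init__(self) -> None:
        n_alleles = 1 + len(self.alts)
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for name, depths in (("pool1", self.depths_pool1), ("pool2", self.depths_pool2)):
            if len(depths) != n_alleles:
                raise ValueError(
                    f"{name} has {len(depths)} depth entries for {n_alleles} alleles"
                )
            if any(d < 0 for d in depths):
                raise ValueError(f"{name} has negative depths: {depths}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}"

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass(frozen=True)
class EDRecord:
    """ED result for one site: frequency vectors and their distance."""

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    freqs_pool1: tuple[float, ...]
    freqs_pool2: tuple[float, ...]
    ed: float


def allele_frequencies(
    variant: PooledVariant, min_depth: int = 10
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-pool allele-frequency vectors, or ``None`` when under-covered.

    The frequency of allele *a* in pool *p* is its read depth divided by
    the pool's total depth at the site.  A site where either pool's total
    depth is below ``min_depth`` is flagged by returning ``None`` and is
    excluded from the scan.

    Raises
    ------
    ValueError
        If ``min_depth`` is negative, or if ``min_depth == 0`` and a pool
        has zero total depth (the frequency is undefined).
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    d1 = np.asarray(variant.depths_pool1, dtype=float)
    d2 = np.asarray(variant.depths_pool2, dtype=float)
    t1, t2 = d1.sum(), d2.sum()
    if min_depth == 0 and (t1 == 0 or t2 == 0):
        raise ValueError(f"undefined frequency: zero total depth at {variant.variant_id}")
    if t1 < min_depth or t2 < min_depth:
        return None
    return d1 / t1, d2 / t2


def compute_ed(freqs_a: Sequence[float], freqs_b: Sequence[float]) -> float:
    """Euclidean distance between two allele-frequency vectors.

    For a biallelic site this equals ``sqrt(2) * |delta_f|`` where
    ``delta_f`` is the difference in alternate-allele frequency.
    """
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frequency vector length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def ed_scan(
    variants: Sequence[PooledVariant],
    min_depth: int = 10,
    ed_min: float = DEFAULT_ED_MIN,
) -> list[EDRecord]:
    """Compute ED for every adequately covered site and screen by ED.

    Sites where either pool's depth is below ``min_depth`` are dropped;
    sites with ED strictly below ``ed_min`` are removed (ED equal to the
    threshold is retained).  Returns one :class:`EDRecord` per retained
    site, in input order.
    """
    retained: list[EDRecord] = []
    for v in variants:
        freqs = allele_frequencies(v, min_depth=min_depth)
        if freqs is None:
            continue
        f1, f2 = freqs
        ed = compute_ed(f1, f2)
        if ed < ed_min:
            continue
        retained.append(
            EDRecord(
                variant_id=v.variant_id,
                chrom=v.chrom,
                pos=v.pos,
                ref=v.ref,
                alts=v.alts,
                freqs_pool1=tuple(f1),
                freqs_pool2=tuple(f2),
                ed=ed,
            )
        )
    return retained


def ed_table(
    variants: Sequence[PooledVariant],
    min_depth: int = 10,
    ed_min: float = DEFAULT_ED_MIN,
    top_q: float | None = 0.05,
    universe: Literal["retained", "all_snps"] = "retained",
) -> pd.DataFrame:
    """Full per-site ED table with retention and outlier flags.

    Unlike :func:`ed_scan` this reports every site, including those
    failing the depth or ED screens, so the output is suitable for
    writing as the scan's primary TSV.  Outlier flags mark retained
    sites in the top ``top_q`` fraction by ED (ties at the cutoff
    included); the quantile is taken over the retained sites by default
    or over every scanned site with ``universe="all_snps"``.
    """
    rows = []
    for v in variants:
        freqs = allele_frequencies(v, min_depth=min_depth)
        if freqs is None:
            rows.append((v.chrom, v.pos, v.ref, ",".join(v.alts), np.nan, np.nan, np.nan, False))
            continue
        f1, f2 = freqs
        ed = compute_ed(f1, f2)
        # f1/f2 columns report the first alternate allele's frequency
        rows.append(
            (v.chrom, v.pos, v.ref, ",".join(v.alts), f1[1], f2[1], ed, ed >= ed_min)
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "f1", "f2", "ed", "retained"]
    )
    df["outlier"] = False
    if top_q is not None and df["retained"].any():
        pool = df["ed"].dropna() if universe == "all_snps" else df.loc[df["retained"], "ed"]
        k = math.ceil(top_q * len(pool))
        cutoff = pool.nlargest(k).iloc[-1]
        df.loc[df["retained"] & (df["ed"] >= cutoff), "outlier"] = True
    return df


def top_percentile(
    records: Sequence[EDRecord],
    q: float = 0.05,
    universe: Literal["retained", "all_snps"] = "retained",
    all_records: Sequence[EDRecord] | None = None,
) -> list[EDRecord]:
    """Sites in the top ``q`` fraction by ED, ties at the cutoff included.

    The cutoff is the ED of the ``ceil(q * n)``-th largest record in the
    chosen universe: the post-screening records themselves
    (``"retained"``, the default) or a caller-supplied unscreened set
    (``"all_snps"``, via ``all_records``).  Every record in ``records``
    with ED at or above the cutoff is returned.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if not records:
        raise ValueError("no records to rank")
    if universe == "all_snps":
        if all_records is None:
            raise ValueError('universe="all_snps" requires all_records')
        pool = all_records
    else:
        pool = records
    eds = sorted((r.ed for r in pool), reverse=True)
    k = math.ceil(q * len(eds))
    cutoff = eds[k - 1]
    return [r for r in records if r.ed >= cutoff]


def ed_class_histogram(records: Sequence[EDRecord]) -> dict[str, float]:
    """Fraction of retained sites in each ED class.

    Bins: [0.3,0.4), [0.4,0.5), [0.5,0.6), [0.6,0.7), [0.7,0.8) and
    [0.8, sqrt(2)].  Every record must already have passed the ED >= 0.3
    screen; fractions sum to 1.
    """
    if not records:
        raise ValueError("empty record list")
    counts = {name: 0 for name, _, _ in ED_CLASS_BINS}
    for r in records:
        if r.ed < DEFAULT_ED_MIN:
            raise ValueError(f"record {r.variant_id} has ED {r.ed} < 0.3")
        for name, lo, hi in ED_CLASS_BINS:
            if lo <= r.ed < hi:
                counts[name] += 1
                break
    n = len(records)
    return {name: c / n for name, c in counts.items()}


def ranking_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve of a score ranking true-vs-false labels.

    Computed as the Mann-Whitney U statistic scaled by n_pos * n_neg,
    i.e. the probability that a random positive outranks a random
    negative (ties count half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    from scipy import stats

    u = stats.mannwhitneyu(scores[labels], scores[~labels], alternative="two-sided")
    return float(u.statistic) / (n_pos * n_neg)


def read_pooled_vcf(
    path: str,
    sample_pool1: str | None = None,
    sample_pool2: str | None = None,
) -> list[PooledVariant]:
    """Read a two-sample VCF with per-sample AD into PooledVariant records.

    Sample order defaults to file order (first sample = selected pool);
    pass sample names to override.
    """
    variants: list[PooledVariant] = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        if len(samples) < 2:
            raise ValueError(f"need two pool samples, VCF has {samples}")
        s1 = sample_pool1 or samples[0]
        s2 = sample_pool2 or samples[1]
        for rec in vf:
            ad1 = rec.samples[s1].get("AD")
            ad2 = rec.samples[s2].get("AD")
            if ad1 is None or ad2 is None:
                raise ValueError(f"missing AD at {rec.chrom}:{rec.pos}")
            variants.append(
                PooledVariant(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    depths_pool1=tuple(int(d) for d in ad1),
                    depths_pool2=tuple(int(d) for d in ad2),
                )
            )
    return variants


def write_ed_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
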