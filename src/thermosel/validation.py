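"""qPCR validation: Livak relative quantification and association tests.

Relative expression follows the Livak method with perfect doubling per
cycle: ΔCt = Ct(target) − Ct(reference), ΔΔCt = ΔCt − calibrator ΔCt,
RQ = 2^−ΔΔCt.  The calibrator is the mean control-group ΔCt at the
matching timepoint, so the control group self-calibrates to a mean RQ
of 1.  Built on top of RQ are a basal (0 h) group comparison, a
plasticity-range metric over the heat-shock time course, and a
genotype-expression association (Kruskal-Wallis + pairwise
Mann-Whitney).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RelativeExpression",
    "relative_quantity",
    "rq_table",
    "basal_expression_compare",
    "plasticity_range",
    "genotype_expression_test",
]


@dataclass(frozen=True)
class RelativeExpression:
    """Livak relative quantity for one sample x gene measurement."""

    sample: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    rq: float


def relative_quantity(
    sample: str,
    gene: str,
    ct_target: float,
    ct_reference: float,
    calibrator_delta_ct: float,
) -> RelativeExpression:
    """RQ = 2^−ΔΔCt for one measurement.

    ``calibrator_delta_ct`` is the reference condition's mean ΔCt
    (typically the control group at the same timepoint).
    """
    if not np.isfinite(ct_reference):
        raise ValueError(f"{sample}/{gene}: missing reference Ct")
    dct = ct_target - ct_reference
    ddct = dct - calibrator_delta_ct
    return RelativeExpression(
        sample=sample, gene=gene, delta_ct=dct, delta_delta_ct=ddct,
        rq=float(2.0 ** (-ddct)),
    )


def rq_table(
    ct: pd.DataFrame,
    calibrator_group: str = "control",
    calibrator_mode: Literal["control_within_timepoint", "timepoint0_within_group"]
    = "control_within_timepoint",
    aggregate: Literal["mean", "median"] = "mean",
) -> pd.DataFrame:
    """Relative quantities for a whole Ct table.

    ``ct`` needs columns sample, group, timepoint, gene, ct_target,
    ct_reference (genotype optional).  Two calibration modes:

    - ``control_within_timepoint`` (default): each measurement is
      calibrated against the control group's aggregate ΔCt for the same
      gene and timepoint.
    - ``timepoint0_within_group``: calibrated against the same group's
      aggregate ΔCt at 0 h, expressing induction relative to the
      pre-shock state.
    """
    df = ct.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]
    agg = "mean" if aggregate == "mean" else "median"
    if calibrator_mode == "control_within_timepoint":
        cal = (
            df[df["group"] == calibrator_group]
            .groupby(["gene", "timepoint"])["delta_ct"]
            .agg(agg)
            .rename("calibrator_delta_ct")
        )
        df = df.join(cal, on=["gene", "timepoint"])
    else:
        cal = (
            df[df["timepoint"] == 0]
            .groupby(["gene", "group"])["delta_ct"]
            .agg(agg)
            .rename("calibrator_delta_ct")
        )
        df = df.join(cal, on=["gene", "group"])
    if df["calibrator_delta_ct"].isna().any():
        raise ValueError("calibrator ΔCt unavailable for some gene/timepoint strata")
    df["delta_delta_ct"] = df["delta_ct"] - df["calibrator_delta_ct"]
    df["rq"] = 2.0 ** (-df["delta_delta_ct"])
    return df


def basal_expression_compare(
    rq: pd.DataFrame, group_a: str = "selected", group_b: str = "control"
) -> pd.DataFrame:
    """Per-gene basal (0 h) comparison of RQ between groups.

    Welch t-test on log2(RQ); reports group means of RQ with standard
    errors and the two-sided p-value, one row per gene.
    """
    basal = rq[rq["timepoint"] == 0]
    rows = []
    for gene, sub in basal.groupby("gene"):
        xa = sub.loc[sub["group"] == group_a, "rq"].to_numpy()
        xb = sub.loc[sub["group"] == group_b, "rq"].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"{gene}: need >=2 samples per group at 0 h")
        _, p = stats.ttest_ind(np.log2(xa), np.log2(xb), equal_var=False)
        rows.append(
            (gene, xa.mean(), xa.std(ddof=1) / np.sqrt(len(xa)),
             xb.mean(), xb.std(ddof=1) / np.sqrt(len(xb)), float(p))
        )
    return pd.DataFrame(
        rows,
        columns=["gene", f"mean_{group_a}", f"se_{group_a}",
                 f"mean_{group_b}", f"se_{group_b}", "pvalue"],
    )


def plasticity_range(rq: pd.DataFrame) -> float:
    """Induction plasticity: max − min of per-timepoint mean RQ.

    ``rq`` holds the RQ values of one group x gene over the time course;
    a small range means the gene barely responds to the stimulus.
    """
    means = rq.groupby("timepoint")["rq"].mean()
    if len(means) < 2:
        raise ValueError("plasticity range needs >=2 timepoints")
    return float(means.max() - means.min())


def genotype_expression_test(
    rq: pd.DataFrame, min_per_genotype: int = 3
) -> dict:
    """Association between genotype and relative expression for one gene.

    Kruskal-Wallis omnibus test over genotype classes, pairwise
    Mann-Whitney with Benjamini-Hochberg correction, and the genotype
    ranking by mean RQ.  Genotype classes with fewer than
    ``min_per_genotype`` samples are dropped with a warning.
    """
    groups = {g: sub["rq"].to_numpy() for g, sub in rq.groupby("genotype")}
    small = [g for g, x in groups.items() if len(x) < min_per_genotype]
    for g in small:
        warnings.warn(f"genotype {g} dropped: only {len(groups[g])} sample(s)")
        del groups[g]
    if len(groups) < 2:
        raise ValueError("need >=2 genotype classes with enough samples")
    labels = sorted(groups, key=lambda g: -float(np.mean(groups[g])))
    omnibus_p = float(stats.kruskal(*[groups[g] for g in labels]).pvalue)
    pairs = list(combinations(labels, 2))
    raw = [
        float(stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided").pvalue)
        for a, b in pairs
    ]
    adj = multipletests(raw, method="fdr_bh")[1] if raw else []
    return {
        "means": {g: float(np.mean(groups[g])) for g in labels},
        "ranking": labels,
        "omnibus_p": omnibus_p,
        "pairwise": {
            f"{a}|{b}": {"pvalue": r, "padj": float(q)}
            for (a, b), r, q in zip(pairs, raw, adj)
        },
    }
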