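"""Respirometry and survival summaries.

The respiration rate of a closed-chamber trial is the (negated) slope
of dissolved oxygen against time, estimated by ordinary least squares
and reported in mg/mL/h.  Survival trials are summarised as per-cage
percentages with group means, standard errors and a Welch t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RateFit",
    "respiration_rate",
    "compare_rates",
    "survival_summary",
    "heatshock_recovery_rate",
]


@dataclass(frozen=True)
class RateFit:
    """OLS respiration-rate estimate with fit diagnostics."""

    rate_mg_per_ml_h: float
    slope_per_h: float
    intercept: float
    r_squared: float
    residual_sd: float
    stderr_per_h: float
    degenerate: bool = False  # constant trace: R^2 undefined, reported as 0


def respiration_rate(
    times_s: np.ndarray | pd.Series, o2_mg_per_ml: np.ndarray | pd.Series
) -> RateFit:
    """Respiration rate = −slope of an OLS fit of O2 on time, per hour.

    Requires at least 10 points; warns when sampling is not uniformly
    spaced.  On a constant trace the rate is 0 and R² is reported as 0
    with the ``degenerate`` flag set.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(o2_mg_per_ml, dtype=float)
    if t.size < 10:
        raise ValueError(f"need >=10 time points, got {t.size}")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0]):
        warnings.warn("non-uniform sampling interval in respirometry trace")
    t_h = t / 3600.0
    if np.allclose(y, y[0]):
        return RateFit(
            rate_mg_per_ml_h=0.0, slope_per_h=0.0, intercept=float(y[0]),
            r_squared=0.0, residual_sd=0.0, stderr_per_h=0.0, degenerate=True,
        )
    fit = stats.linregress(t_h, y)
    resid = y - (fit.intercept + fit.slope * t_h)
    return RateFit(
        rate_mg_per_ml_h=float(-fit.slope),
        slope_per_h=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        residual_sd=float(np.std(resid, ddof=2)),
        stderr_per_h=float(fit.stderr),
    )


def rates_by_subject(traces: pd.DataFrame) -> pd.DataFrame:
    """Fit one respiration rate per subject from a long-format trace table."""
    rows = []
    for (subject, group), sub in traces.groupby(["subject", "group"], sort=True):
        fit = respiration_rate(sub["time_s"], sub["o2_mg_per_ml"])
        rows.append((subject, group, fit.rate_mg_per_ml_h, fit.r_squared))
    return pd.DataFrame(rows, columns=["subject", "group", "rate_mg_per_ml_h", "r_squared"])


def compare_rates(
    rates: pd.DataFrame, group_a: str = "selected", group_b: str = "control"
) -> dict:
    """Group means ± SE of per-subject rates and a two-sided Welch t-test."""
    xa = rates.loc[rates["group"] == group_a, "rate_mg_per_ml_h"].to_numpy()
    xb = rates.loc[rates["group"] == group_b, "rate_mg_per_ml_h"].to_numpy()
    if len(xa) < 2 or len(xb) < 2:
        raise ValueError("need >=2 subjects per group")
    _, p = stats.ttest_ind(xa, xb, equal_var=False)
    return {
        group_a: {"mean": float(xa.mean()), "se": float(xa.std(ddof=1) / np.sqrt(len(xa))),
                  "n": len(xa)},
        group_b: {"mean": float(xb.mean()), "se": float(xb.std(ddof=1) / np.sqrt(len(xb))),
                  "n": len(xb)},
        "mean_difference": float(xa.mean() - xb.mean()),
        "pvalue": float(p),
    }


def survival_summary(
    records: pd.DataFrame, day: int, group_a: str = "selected", group_b: str = "control"
) -> dict:
    """Per-group mean survival % across cages at a given day, with Welch p.

    ``records`` is long format with columns cage, group, day, n_initial,
    n_alive; per-cage survival % = 100 * n_alive / n_initial.
    """
    at_day = records[records["day"] == day]
    if at_day.empty:
        raise ValueError(f"no survival records at day {day}")
    pct = (
        at_day.assign(pct=100.0 * at_day["n_alive"] / at_day["n_initial"])
        .groupby(["group", "cage"])["pct"]
        .first()
    )
    out: dict = {"day": day}
    samples = {}
    for g in (group_a, group_b):
        x = pct.loc[g].to_numpy()
        if len(x) < 2:
            raise ValueError(f"group {g}: need >=2 cages")
        samples[g] = x
        out[g] = {
            "mean_pct": float(x.mean()),
            "se_pct": float(x.std(ddof=1) / np.sqrt(len(x))),
            "min_pct": float(x.min()),
            "max_pct": float(x.max()),
            "n_cages": len(x),
        }
    _, p = stats.ttest_ind(samples[group_a], samples[group_b], equal_var=False)
    out["mean_difference_pct"] = float(samples[group_a].mean() - samples[group_b].mean())
    out["pvalue"] = float(p)
    return out


def heatshock_recovery_rate(n_initial: int, n_surviving: int) -> float:
    """Percent of animals surviving the recovery period after acute heat shock."""
    if n_initial <= 0:
        raise ValueError("n_initial must be positive")
    if n_surviving > n_initial:
        raise ValueError("more survivors than initial animals")
    return 100.0 * n_surviving / n_initial
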