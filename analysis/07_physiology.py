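#!/usr/bin/env python
"""Physiology summaries: respiration rates and field survival.

Fits one OLS slope per O2 trace (rate in mg/mL/h), compares groups with
a Welch t-test, and summarises the field survival trial at day 120 as
per-cage percentages with group means and a Welch t-test.
"""

import json
from pathlib import Path

import pandas as pd

from thermosel import physiology

DATA = Path("results/data")
OUT = Path("results/physiology")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    traces = pd.read_csv(DATA / "respirometry.tsv", sep="\t")
    rates = physiology.rates_by_subject(traces)
    rates.to_csv(OUT / "respiration_rates.tsv", sep="\t", index=False)
    comp = physiology.compare_rates(rates)
    print(f"respiration at 20 degC: selected {comp['selected']['mean']:.2g} "
          f"+/- {comp['selected']['se']:.1g} vs control "
          f"{comp['control']['mean']:.2g} +/- {comp['control']['se']:.1g} "
          f"mg/mL/h (p = {comp['pvalue']:.2g})")

    survival = pd.read_csv(DATA / "survival.tsv", sep="\t")
    surv = physiology.survival_summary(survival, day=120)
    print(f"summer survival: selected {surv['selected']['mean_pct']:.1f}% "
          f"({surv['selected']['min_pct']:.0f}-{surv['selected']['max_pct']:.0f}%) "
          f"vs control {surv['control']['mean_pct']:.1f}% "
          f"({surv['control']['min_pct']:.0f}-{surv['control']['max_pct']:.0f}%), "
          f"p = {surv['pvalue']:.2g}")
    (OUT / "summary.json").write_text(
        json.dumps({"respiration": comp, "survival": surv}, indent=2, sort_keys=True)
    )


if __name__ == "__main__":
    main()
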