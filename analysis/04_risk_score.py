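#!/usr/bin/env python
"""Risk stratification: indicator tertiles, combined score, KM comparison.

Rebuilds the cohort of 03_survival_models.py, stratifies the immunodrop
into tertiles, assigns the 3-point combined risk score (G3 grade + tumor
history + medium-or-high ID) and compares recurrence-free survival across
the low / intermediate / high score groups with pairwise log-rank tests.
Writes results/km_risk_*.csv, results/risk_scores.csv and prints the group
table.
"""

import sys
from pathlib import Path

import pandas as pd

from immunogradient import CohortSpec, censor_rfs, km_logrank, simulate_cohort
from immunogradient.survival import score_cohort

RESULTS = Path("results")
SEED = 7


def main() -> None:
    ind_path = RESULTS / "slide_indicators.csv"
    if not ind_path.exists():
        print("run analysis/02_spatial_gradients.py first", file=sys.stderr)
        return 1
    indicators = pd.read_csv(ind_path)
    cohort = censor_rfs(
        simulate_cohort(
            CohortSpec(n=157, seed=SEED),
            id_values=indicators["id_10_20um"].to_numpy(),
        )
    )
    scored = score_cohort(cohort)
    scored.to_csv(RESULTS / "risk_scores.csv", index=False)

    tab = (
        scored.groupby("risk_category")
        .agg(n=("event", "size"), events=("event", "sum"),
             median_rfs=("rfs_months", "median"))
        .reindex(["low", "intermediate", "high"])
    )
    print(tab.to_string())

    curves, pvals = km_logrank(scored, scored["risk_category"])
    for name, curve in curves.items():
        curve.to_csv(RESULTS / f"km_risk_{name}.csv", index=False)
    print("\npairwise log-rank:")
    for _, row in pvals.iterrows():
        print(f"  {row['group_a']:12s} vs {row['group_b']:12s} p = {row['p']:.4f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
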