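#!/usr/bin/env python
"""Summarize budgets by island and habitat.

Produces the per-stratum table (mean gross calcification, erosion and net
production with 95% confidence half-widths over sites), pooled outer strata,
across-island habitat means, and the grand mean; writes
results/habitat_summary.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from reefbudget import summarize_by_habitat

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--budgets", type=Path,
                    default=ROOT / "results" / "budgets.csv")
    ap.add_argument("--out", type=Path,
                    default=ROOT / "results" / "habitat_summary.csv")
    args = ap.parse_args()

    if not args.budgets.exists():
        raise SystemExit(f"{args.budgets} missing; run 02_compute_budgets.py")
    budgets = pd.read_csv(args.budgets)
    summary = summarize_by_habitat(budgets, weighting="site")
    summary.to_csv(args.out, index=False)

    print(summary.round(3).to_string(index=False))
    grand = summary[(summary.island == "All") & (summary.habitat == "all")]
    print(f"\nall-habitat mean net production: "
          f"{grand['mean_net'].iloc[0]:.2f} "
          f"(+/- {grand['ci_net'].iloc[0]:.2f}) kg CaCO3 m-2 y-1 "
          f"over {int(grand['n'].iloc[0])} sites")


if __name__ == "__main__":
    main()
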