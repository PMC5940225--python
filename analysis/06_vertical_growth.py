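#!/usr/bin/env python
"""Convert carbonate production to vertical reef growth and assess keep-up.

Calibrates v = Cp + Cp*(Cp*alpha) from the island-wide average conversion
pair (9.7 kg CaCO3 m-2 y-1 corresponds to 7.9 mm y-1), converts the computed
site budgets to potential vertical accretion, and compares against projected
sea-level-rise rates for the RCP scenarios; writes
results/vertical_growth.csv and results/keep_up.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from reefbudget.budget import (calibrate_alpha, keep_up_assessment,
                               vertical_growth)
from reefbudget.constants import RCP_SLR_MM_Y

ROOT = Path(__file__).resolve().parent.parent

CALIBRATION_PAIRS = [(9.7, 7.9)]  # (kg CaCO3 m-2 y-1, mm y-1)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--budgets", type=Path,
                    default=ROOT / "results" / "budgets.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    alpha = calibrate_alpha(CALIBRATION_PAIRS)
    print(f"calibrated alpha = {alpha:.5f} (kg m-2 y-1)^-1 from "
          f"{len(CALIBRATION_PAIRS)} conversion pair(s)")
    print(f"at the peak-site production of 20 kg CaCO3 m-2 y-1: "
          f"{vertical_growth(20.0, alpha):.2f} mm y-1 potential vertical growth")

    if not args.budgets.exists():
        raise SystemExit(f"{args.budgets} missing; run 02_compute_budgets.py")
    budgets = pd.read_csv(args.budgets)
    budgets["vertical_mm_y"] = [
        vertical_growth(max(net, 0.0), alpha) for net in budgets["net"]]
    args.out.mkdir(parents=True, exist_ok=True)
    budgets[["site_id", "island", "habitat", "net", "vertical_mm_y"]].to_csv(
        args.out / "vertical_growth.csv", index=False)

    mean_net = budgets["net"].mean()
    v_mean = vertical_growth(max(mean_net, 0.0), alpha)
    print(f"mean net production {mean_net:.2f} kg CaCO3 m-2 y-1 -> "
          f"{v_mean:.2f} mm y-1")

    rows = []
    for scenario, rate in RCP_SLR_MM_Y.items():
        ok, margin = keep_up_assessment(v_mean, scenario)
        frac = (budgets["vertical_mm_y"] >= rate).mean()
        rows.append({"scenario": scenario, "slr_mm_y": rate,
                     "mean_keeps_up": ok, "margin_mm_y": round(margin, 2),
                     "fraction_of_sites_keeping_up": round(frac, 3)})
        print(f"  {scenario} ({rate} mm y-1): "
              f"{'keeps up' if ok else 'falls behind'} "
              f"(margin {margin:+.1f} mm y-1; "
              f"{frac:.0%} of sites keep up)")
    pd.DataFrame(rows).to_csv(args.out / "keep_up.csv", index=False)


if __name__ == "__main__":
    main()
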