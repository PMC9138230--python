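#!/usr/bin/env python
"""Evolution of PTZ seizure susceptibility over the four testing days.

Summarizes the per-(animal, day) PTZ outcome features of the cohort table:
group mean +/- SD with per-parameter n (animals without the event are
missing, not zero), the percentage of animals seizing per day, and the
within-TBI day-30 vs day-90 latency contrast.

Writes results/ptz_summary.csv and results/ptz_percent_seizing.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from ptemark.stats import cohens_d

ROOT = Path(__file__).resolve().parents[1]
DAYS = (30, 60, 90, 180)
PARAMS = {"A": "latency_first_ed_s", "B": "n_eds", "C": "n_seizures",
          "D": "latency_first_seizure_s", "E": "duration_first_seizure_s"}


def main() -> None:
    cohort_csv = ROOT / "results" / "cohort.csv"
    if not cohort_csv.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    cohort = pd.read_csv(cohort_csv)
    out = ROOT / "results"

    rows = []
    for letter, name in PARAMS.items():
        for day in DAYS:
            col = f"{letter}_d{day}"
            for grp, sub in cohort.groupby("group"):
                vals = sub[col].dropna()
                rows.append({"parameter": name, "day": day, "group": grp,
                             "n": len(vals), "mean": vals.mean(), "sd": vals.std()})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "ptz_summary.csv", index=False)

    seiz_rows = []
    for day in DAYS:
        for grp, sub in cohort.groupby("group"):
            seizing = (sub[f"C_d{day}"] >= 1).sum()
            seiz_rows.append({"day": day, "group": grp, "n_tested": len(sub),
                              "n_seizing": int(seizing),
                              "percent_seizing": 100.0 * seizing / len(sub)})
    seiz = pd.DataFrame(seiz_rows)
    seiz.to_csv(out / "ptz_percent_seizing.csv", index=False)

    tbi = seiz[seiz.group == "tbi"].set_index("day")["percent_seizing"]
    print("TBI percent seizing by day:",
          ", ".join(f"D{d}: {tbi[d]:.0f}%" for d in DAYS))
    ed = cohort[cohort.group == "tbi"]
    d30, d90 = ed["A_d30"].dropna(), ed["A_d90"].dropna()
    d = cohens_d(d30.mean(), d30.std(), len(d30), d90.mean(), d90.std(), len(d90))
    print(f"TBI latency to first ED: D30 {d30.mean():.0f} +/- {d30.std():.0f} s "
          f"-> D90 {d90.mean():.0f} +/- {d90.std():.0f} s (d = {d:.2f})")
    print(f"tables -> {out / 'ptz_summary.csv'}, {out / 'ptz_percent_seizing.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
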