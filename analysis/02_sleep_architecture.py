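#!/usr/bin/env python
"""Sleep-architecture comparison between injured and sham animals.

Recomputes every per-animal sleep metric from the raw hypnograms written by
step 01 (stage times, bout durations, transition categories, fragmentation
indices per lights phase), then compares groups: Mann-Whitney p-values,
Cohen's d, and the direction of the injury effects (more transitions,
higher fragmentation during lights-on, shorter REM bouts).

Writes results/sleep_metrics.csv, results/sleep_metrics_summary.csv and
results/sleep_group_comparison.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from ptemark.pipeline import run_sleep
from ptemark.stats import cohens_d, rank_tests

ROOT = Path(__file__).resolve().parents[1]

COMPARED = ["sfi_total", "sfi_deep_to_light", "total_transitions",
            "transitions_to_N3", "transitions_to_REM", "mean_bout_min_REM",
            "d2l_N3_W", "sleep_h"]


def main() -> None:
    hyp_dir = ROOT / "scratch" / "hypnograms"
    files = sorted(hyp_dir.glob("*.csv"))
    if not files:
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    out = ROOT / "results"
    df = run_sleep(files, out)
    df["group"] = df["animal_id"].str.split("_").str[0]

    rows = []
    for phase in ("on", "off", "combined"):
        sub = df[df.phase == phase]
        sham = sub[sub.group == "sham"]
        tbi = sub[sub.group == "tbi"]
        for col in COMPARED:
            a, b = sham[col].dropna(), tbi[col].dropna()
            p = rank_tests(a, b)["mannwhitney_p"]
            d = cohens_d(a.mean(), a.std(), len(a), b.mean(), b.std(), len(b))
            rows.append({"parameter": col, "phase": phase,
                         "sham_mean": a.mean(), "sham_sd": a.std(),
                         "tbi_mean": b.mean(), "tbi_sd": b.std(),
                         "mwu_p": p, "cohens_d": round(d, 2)})
    cmp_df = pd.DataFrame(rows)
    cmp_df.to_csv(out / "sleep_group_comparison.csv", index=False)

    on = cmp_df[(cmp_df.phase == "on") & (cmp_df.parameter == "sfi_total")].iloc[0]
    rem = cmp_df[(cmp_df.phase == "off") & (cmp_df.parameter == "mean_bout_min_REM")].iloc[0]
    print(f"lights-on fragmentation index: sham {on.sham_mean:.2f} +/- {on.sham_sd:.2f} "
          f"vs TBI {on.tbi_mean:.2f} +/- {on.tbi_sd:.2f} "
          f"(MWU p = {on.mwu_p:.4f}, d = {on.cohens_d})")
    print(f"lights-off REM bout (min): sham {rem.sham_mean:.2f} vs TBI {rem.tbi_mean:.2f} "
          f"({100 * (rem.tbi_mean - rem.sham_mean) / rem.sham_mean:+.0f}%)")
    print(f"group comparison -> {out / 'sleep_group_comparison.csv'}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
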