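#!/usr/bin/env python
"""Combinatory-biomarker evaluation of PTZ and sleep feature panels.

For each contrast (sham vs TBI on the whole cohort; e+ vs e- within the
injured group) and panel (PTZ parameters A-C/A-E per testing day, sleep
panels F-I and F-M), fits a logistic panel score, reports the apparent ROC
AUC, and challenges it with leave-one-out cross-validation: pooled held-out
AUC, BCa bootstrap 95% CI (B = 2000), and threshold-0.5 confusion metrics.
The expected pattern is the one seen in small-cohort biomarker studies:
apparent AUC always exceeds the cross-validated AUC, and weak panels
collapse toward (or below) chance under cross-validation.

Writes results/biomarker_panels.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from ptemark.pipeline import run_biomarker

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260929

PANELS = [
    {"letters": "ABC", "contrast": "is_tbi", "day": 60},
    {"letters": "ABC", "contrast": "is_tbi", "day": 90},
    {"letters": "ABCDE", "contrast": "is_tbi", "day": 90},
    {"letters": "ABC", "contrast": "eplus", "day": 90},
    {"letters": "ABC", "contrast": "eplus", "day": 180},
    {"letters": "FGHI", "contrast": "is_tbi"},
    {"letters": "FGHIJKLM", "contrast": "is_tbi"},
    {"letters": "FGHI", "contrast": "eplus"},
]


def main() -> None:
    cohort_csv = ROOT / "results" / "cohort.csv"
    if not cohort_csv.exists():
        print("run analysis/01_simulate_cohort.py first", file=sys.stderr)
        return 1
    cohort = pd.read_csv(cohort_csv)
    df = run_biomarker(cohort, PANELS, ROOT / "results", seed=SEED, B=2000)

    show = df[["panel", "day", "contrast", "n_pos", "n_neg",
               "apparent_auc", "cv_auc", "cv_ci_lo", "cv_ci_hi",
               "misclassification_rate"]].round(3)
    print(show.to_string(index=False))
    shrunk = (df.apparent_auc - df.cv_auc).mean()
    print(f"\nmean optimism (apparent - cross-validated AUC): {shrunk:+.3f}")
    best = df.loc[df.cv_auc.idxmax()]
    print(f"best cross-validated panel: {best.panel} ({best.contrast}"
          + (f", D{best.day:.0f}" if pd.notna(best.day) else "")
          + f") cv AUC {best.cv_auc:.3f} [{best.cv_ci_lo:.3f}, {best.cv_ci_hi:.3f}]")
    return 0


if __name__ == "__main__":
    sys.exit(main())
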