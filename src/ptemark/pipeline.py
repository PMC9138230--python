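"""Report assembly: per-animal tables, group summaries, biomarker panels.

These functions take file paths or in-memory tables and write the CSV
reports mirroring the study's table shapes: per-animal sleep metrics plus
group mean +/- SD, per-(animal, day) PTZ outcomes plus per-day seizing
percentages, and the Table-5-style combinatory-biomarker report (apparent
AUC, cross-validated AUC with 95% CI, misclassification, sensitivity,
specificity, precision). Every run can write a manifest (config hash, seed,
package version) sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .biomarkers import FeaturePanel, evaluate_panel
from .hypnogram import read_hypnogram
from .ptz import EEGEvent, outcome_frame, percent_seizing, ptz_outcomes
from .sleep import metrics_frame, sleep_metrics_record
from .simulate import FEATURE_LETTERS, SLEEP_FEATURES

log = logging.getLogger("ptemark")

__all__ = ["run_sleep", "run_ptz", "run_biomarker", "write_manifest", "panel_columns"]


def write_manifest(out_dir: Path, config: dict) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "ptemark_version": __version__,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path


def run_sleep(hypnogram_paths: Sequence[Path], out_dir: Path) -> pd.DataFrame:
    """Per-animal sleep metrics and a group summary table.

    Writes sleep_metrics.csv (one row per animal-phase) and
    sleep_metrics_summary.csv (mean +/- SD over animals per phase).
    """
    paths = [Path(p) for p in hypnogram_paths]
    missing = [str(p) for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"hypnogram files not found: {missing}")
    if not paths:
        raise ValueError("no hypnogram files given")
    records = [sleep_metrics_record(read_hypnogram(p)) for p in paths]
    df = metrics_frame(records)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "sleep_metrics.csv", index=False)
    num = df.drop(columns=["animal_id"]).groupby("phase")
    summary = num.agg(["mean", "std", "count"])
    summary.columns = ["_".join(c) for c in summary.columns]
    summary.to_csv(out_dir / "sleep_metrics_summary.csv")
    log.info("sleep metrics for %d animals -> %s", len(records), out_dir)
    return df


def run_ptz(events: pd.DataFrame, out_dir: Path, window_s: float = 3600.0) -> pd.DataFrame:
    """Per-(animal, day) PTZ outcomes and per-day seizing percentages.

    `events` is the long event table (animal_id, day, onset_s, duration_s
    [, racine]). Animals without seizures keep missing latency columns —
    never zeros.
    """
    outcomes = []
    for (animal, day), grp in events.groupby(["animal_id", "day"], sort=True):
        evs = [
            EEGEvent(
                onset_s=float(r.onset_s),
                duration_s=float(r.duration_s),
                racine=None
                if "racine" not in grp.columns or pd.isna(r.racine)
                else int(r.racine),
            )
            for r in grp.itertuples()
        ]
        outcomes.append(
            ptz_outcomes(evs, animal_id=str(animal), day=int(day), window_s=window_s)
        )
    df = outcome_frame(outcomes)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "ptz_outcomes.csv", index=False)
    days = sorted(df["day"].unique())
    seizing = pd.DataFrame(
        {
            "day": days,
            "n_tested": [int((df["day"] == d).sum()) for d in days],
            "n_seizing": [
                int(((df["day"] == d) & (df["n_seizures"] >= 1)).sum()) for d in days
            ],
            "percent_seizing": [percent_seizing(outcomes, d) for d in days],
        }
    )
    seizing.to_csv(out_dir / "ptz_percent_seizing.csv", index=False)
    log.info("PTZ outcomes for %d sessions -> %s", len(df), out_dir)
    return df


def panel_columns(letters: str, day: Optional[int] = None) -> list[str]:
    """Map Table-5 feature letters (A-M) to cohort-table column names."""
    cols = []
    for ch in letters:
        if ch in FEATURE_LETTERS:
            if day is None:
                raise ValueError(f"PTZ feature {ch} needs a testing day")
            cols.append(f"{ch}_d{day}")
        elif ch in SLEEP_FEATURES:
            cols.append(ch)
        else:
            raise KeyError(f"unknown feature letter {ch!r} (expected A-M)")
    return cols


def run_biomarker(
    cohort: pd.DataFrame,
    panels: Sequence[dict],
    out_dir: Path,
    seed: int = 0,
    B: int = 2000,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Evaluate combinatory-biomarker panels; Table-5-shaped CSV output.

    Each panel dict has keys: letters (e.g. "ABC"), contrast (label column,
    e.g. "is_tbi" / "eplus" / "pte"), and optionally day. Deterministic
    under (cohort, seed).
    """
    rows = []
    for spec_ in panels:
        letters = spec_["letters"]
        contrast = spec_["contrast"]
        day = spec_.get("day")
        cols = panel_columns(letters, day)
        sub = cohort[cohort[contrast].notna()]
        panel = FeaturePanel.from_frame(
            sub, cols, contrast, contrast_name=f"{contrast}:{letters}"
            + (f"_d{day}" if day else "")
        )
        ev = evaluate_panel(panel, seed=seed, B=B, threshold=threshold)
        if ev.cv_auc > ev.apparent_auc:
            log.warning(
                "%s: cross-validated AUC (%.3f) exceeds apparent AUC (%.3f)",
                ev.contrast_name, ev.cv_auc, ev.apparent_auc,
            )
        rows.append(
            {
                "panel": letters,
                "day": day,
                "contrast": contrast,
                "n_pos": ev.n_pos,
                "n_neg": ev.n_neg,
                "apparent_auc": ev.apparent_auc,
                "cv_auc": ev.cv_auc,
                "cv_ci_lo": ev.cv_ci[0],
                "cv_ci_hi": ev.cv_ci[1],
                "misclassification_rate": ev.misclassification_rate,
                "sensitivity": ev.sensitivity,
                "specificity": ev.specificity,
                "precision": math.nan if ev.precision is None else ev.precision,
                "seed": seed,
            }
        )
    df = pd.DataFrame(rows)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(out_dir / "biomarker_panels.csv", index=False)
    log.info("evaluated %d panels -> %s", len(df), out_dir)
    return df
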