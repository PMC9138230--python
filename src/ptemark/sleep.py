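"""Sleep-architecture metrics from epoch-scored hypnograms.

Implements the per-animal sleep parameters of a 24-h rodent recording:
stage times (h), mean bout durations (min), the 4x4 stage-transition count
matrix and its derived categories (transitions into each stage; the six
deep-to-light ordered pairs), and the sleep fragmentation index (SFI) —
transitions per hour of recording — in a total and a deep-to-light variant.

Depth order is W < N2 < N3 < REM; "deep-to-light" means any transition from a
deeper stage to a strictly lighter one (N2->W, N3->W, REM->W, N3->N2,
REM->N2, REM->N3).

All metrics are reported separately for the lights-on and lights-off periods
and for both combined. Per-phase counts exclude transitions spanning a phase
boundary; combined counts include them (so combined need not equal the sum
of the two phases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, Phase, Stage, STAGES

__all__ = [
    "TransitionSummary",
    "SleepMetricsRecord",
    "stage_durations",
    "bouts",
    "mean_bout_duration",
    "transition_summary",
    "deep_to_light_counts",
    "sfi",
    "sleep_metrics_record",
    "metrics_frame",
    "DEEP_TO_LIGHT_PAIRS",
]

DEEP_TO_LIGHT_PAIRS = (
    (Stage.N2, Stage.W),
    (Stage.N3, Stage.W),
    (Stage.REM, Stage.W),
    (Stage.N3, Stage.N2),
    (Stage.REM, Stage.N2),
    (Stage.REM, Stage.N3),
)

_IDX = {s: i for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class TransitionSummary:
    """4x4 stage-change counts (from_stage, to_stage) with zero diagonal."""

    counts: np.ndarray  # shape (4, 4), int
    duration_h: float

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (4, 4):
            raise ValueError("counts must be 4x4")
        if np.any(np.diag(c) != 0):
            raise ValueError("diagonal must be zero: a transition is a stage change")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def transitions_to(self, stage: Stage) -> int:
        return int(self.counts[:, _IDX[stage]].sum())

    def transitions_from(self, stage: Stage) -> int:
        return int(self.counts[_IDX[stage], :].sum())


def stage_durations(hyp: Hypnogram) -> dict[Stage, float]:
    """Hours spent in each stage; values sum to the recording duration."""
    per_epoch_h = hyp.epoch_length_s / 3600.0
    out = {s: 0.0 for s in STAGES}
    for s in hyp.stages:
        out[s] += per_epoch_h
    return out


def bouts(hyp: Hypnogram) -> list[tuple[Stage, int, int]]:
    """Maximal same-stage runs as (stage, start_epoch, length_epochs).

    The runs partition the epoch sequence; adjacent runs differ in stage.
    Bouts truncated by the recording edges are included.
    """
    out: list[tuple[Stage, int, int]] = []
    start = 0
    for i in range(1, len(hyp) + 1):
        if i == len(hyp) or hyp.stages[i] is not hyp.stages[start]:
            out.append((hyp.stages[start], start, i - start))
            start = i
    return out


def mean_bout_duration(hyp: Hypnogram, stage: Stage) -> Optional[float]:
    """Mean duration (minutes) of maximal runs of `stage`; None if absent."""
    runs = [ln for s, _, ln in bouts(hyp) if s is stage]
    if not runs:
        return None
    total_min = sum(runs) * hyp.epoch_length_s / 60.0
    return total_min / len(runs)


def transition_summary(
    hyp: Hypnogram, respect_phase_boundaries: bool = False
) -> TransitionSummary:
    """Count stage changes at consecutive-epoch boundaries.

    With ``respect_phase_boundaries``, boundaries where the lights phase
    changes are skipped, making per-phase counts well defined.
    """
    counts = np.zeros((4, 4), dtype=int)
    for i in range(len(hyp) - 1):
        a, b = hyp.stages[i], hyp.stages[i + 1]
        if a is b:
            continue
        if respect_phase_boundaries and hyp.phase[i] is not hyp.phase[i + 1]:
            continue
        counts[_IDX[a], _IDX[b]] += 1
    return TransitionSummary(counts=counts, duration_h=hyp.duration_h)


def deep_to_light_counts(ts: TransitionSummary) -> dict[tuple[Stage, Stage], int]:
    """The six deep-to-light transition counts under depth order W<N2<N3<REM."""
    return {
        (a, b): int(ts.counts[_IDX[a], _IDX[b]]) for a, b in DEEP_TO_LIGHT_PAIRS
    }


def sfi(ts: TransitionSummary) -> tuple[float, float]:
    """(sfi_total, sfi_deep_to_light): transitions per hour of recording."""
    if ts.duration_h <= 0:
        raise ValueError("zero duration")
    d2l = sum(deep_to_light_counts(ts).values())
    return ts.total / ts.duration_h, d2l / ts.duration_h


def _phase_mask_summary(hyp: Hypnogram, phase: Optional[Phase]) -> Optional[TransitionSummary]:
    """Transition summary restricted to one phase (or combined when None).

    Per-phase: boundaries are counted only when both epochs are in `phase`;
    duration is the time spent in that phase.
    """
    if phase is None:
        return transition_summary(hyp, respect_phase_boundaries=False)
    counts = np.zeros((4, 4), dtype=int)
    n_phase = sum(1 for p in hyp.phase if p is phase)
    if n_phase == 0:
        return None
    for i in range(len(hyp) - 1):
        if hyp.phase[i] is not phase or hyp.phase[i + 1] is not phase:
            continue
        a, b = hyp.stages[i], hyp.stages[i + 1]
        if a is not b:
            counts[_IDX[a], _IDX[b]] += 1
    duration_h = n_phase * hyp.epoch_length_s / 3600.0
    return TransitionSummary(counts=counts, duration_h=duration_h)


def _phase_segments(hyp: Hypnogram, phase: Phase) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs of epochs in `phase`."""
    segs = []
    start = None
    for i, p in enumerate(hyp.phase):
        if p is phase and start is None:
            start = i
        elif p is not phase and start is not None:
            segs.append((start, i))
            start = None
    if start is not None:
        segs.append((start, len(hyp)))
    return segs


PHASES_REPORTED = ("on", "off", "combined")


@dataclass
class SleepMetricsRecord:
    """All per-animal sleep parameters, per reported phase (on/off/combined)."""

    animal_id: str
    sleep_h: dict[str, float] = field(default_factory=dict)
    wake_h: dict[str, float] = field(default_factory=dict)
    stage_time_h: dict[str, dict[Stage, float]] = field(default_factory=dict)
    mean_bout_min: dict[str, dict[Stage, Optional[float]]] = field(default_factory=dict)
    transitions_to: dict[str, dict[Stage, int]] = field(default_factory=dict)
    deep_to_light: dict[str, dict[tuple[Stage, Stage], int]] = field(default_factory=dict)
    total_transitions: dict[str, int] = field(default_factory=dict)
    sfi_total: dict[str, float] = field(default_factory=dict)
    sfi_deep_to_light: dict[str, float] = field(default_factory=dict)
    duration_h: dict[str, float] = field(default_factory=dict)


def sleep_metrics_record(hyp: Hypnogram) -> SleepMetricsRecord:
    """Assemble every reported sleep parameter for one animal.

    Mean bout durations within a phase are computed on contiguous same-phase
    segments, so a bout interrupted by a phase switch is truncated at the
    switch rather than spliced across it.
    """
    rec = SleepMetricsRecord(animal_id=hyp.animal_id)
    for key in PHASES_REPORTED:
        phase = {"on": Phase.LIGHTS_ON, "off": Phase.LIGHTS_OFF, "combined": None}[key]
        ts = _phase_mask_summary(hyp, phase)
        if ts is None:
            continue
        if phase is None:
            seg_hyps = [hyp]
        else:
            seg_hyps = [hyp.subset(range(a, b)) for a, b in _phase_segments(hyp, phase)]
        dur = {s: 0.0 for s in STAGES}
        run_counts = {s: 0 for s in STAGES}
        run_epochs = {s: 0 for s in STAGES}
        for sh in seg_hyps:
            for s, h in stage_durations(sh).items():
                dur[s] += h
            for s, _, ln in bouts(sh):
                run_counts[s] += 1
                run_epochs[s] += ln
        rec.duration_h[key] = ts.duration_h
        rec.stage_time_h[key] = dur
        rec.sleep_h[key] = dur[Stage.N2] + dur[Stage.N3] + dur[Stage.REM]
        rec.wake_h[key] = dur[Stage.W]
        rec.mean_bout_min[key] = {
            s: (run_epochs[s] * hyp.epoch_length_s / 60.0 / run_counts[s])
            if run_counts[s] > 0
            else None
            for s in STAGES
        }
        rec.transitions_to[key] = {s: ts.transitions_to(s) for s in STAGES}
        rec.deep_to_light[key] = deep_to_light_counts(ts)
        rec.total_transitions[key] = ts.total
        s_tot, s_d2l = sfi(ts)
        rec.sfi_total[key] = s_tot
        rec.sfi_deep_to_light[key] = s_d2l
    return rec


def metrics_frame(records: list[SleepMetricsRecord]) -> pd.DataFrame:
    """One row per (animal, phase); columns named after the record fields."""
    rows = []
    for rec in records:
        for key in PHASES_REPORTED:
            if key not in rec.duration_h:
                continue
            row: dict = {"animal_id": rec.animal_id, "phase": key,
                         "duration_h": rec.duration_h[key],
                         "sleep_h": rec.sleep_h[key], "wake_h": rec.wake_h[key]}
            for s in STAGES:
                row[f"stage_time_h_{s.value}"] = rec.stage_time_h[key][s]
                mb = rec.mean_bout_min[key][s]
                row[f"mean_bout_min_{s.value}"] = math.nan if mb is None else mb
                row[f"transitions_to_{s.value}"] = rec.transitions_to[key][s]
            for (a, b), v in rec.deep_to_light[key].items():
                row[f"d2l_{a.value}_{b.value}"] = v
            row["total_transitions"] = rec.total_transitions[key]
            row["sfi_total"] = rec.sfi_total[key]
            row["sfi_deep_to_light"] = rec.sfi_deep_to_light[key]
            rows.append(row)
    return pd.DataFrame(rows)
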