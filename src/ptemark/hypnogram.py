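"""Epoch-scored hypnograms for rodent sleep EEG.

A hypnogram is an ordered sequence of fixed-length epochs (30 s by default),
each labelled with exactly one vigilance stage — awake (W), N2, N3, or REM —
and one lights phase (lights_on / lights_off, 12 h / 12 h cycle). There is no
N1 stage in this scoring scheme. Epochs are indexed from 0; epoch ``i`` spans
``[i*L, (i+1)*L)`` seconds, half-open.

When an epoch contains a mixture of stages, the epoch label is the stage
dominating more than 50% of the epoch duration (:func:`aggregate_epoch`).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "Stage",
    "Phase",
    "SubEpochAnnotation",
    "Hypnogram",
    "aggregate_epoch",
    "read_hypnogram",
    "write_hypnogram",
    "split_by_phase",
]


class Stage(enum.Enum):
    """Vigilance stage. Depth order: W < N2 < N3 < REM.

    REM is ranked deepest: transition taxonomies for this scoring scheme
    list REM->N3 among the deep-to-light categories, which places REM below
    N3 in the depth order.
    """

    W = "W"
    N2 = "N2"
    N3 = "N3"
    REM = "REM"

    @property
    def depth(self) -> int:
        return _DEPTH[self]

    def __lt__(self, other: "Stage") -> bool:
        if not isinstance(other, Stage):
            return NotImplemented
        return self.depth < other.depth


_DEPTH = {Stage.W: 0, Stage.N2: 1, Stage.N3: 2, Stage.REM: 3}

STAGES = (Stage.W, Stage.N2, Stage.N3, Stage.REM)


class Phase(enum.Enum):
    LIGHTS_ON = "lights_on"
    LIGHTS_OFF = "lights_off"


@dataclass(frozen=True)
class SubEpochAnnotation:
    """Stage composition of a single epoch: (stage, duration_s) segments.

    Segment durations must cover the epoch exactly (within 1e-9 s).
    """

    labels: tuple[tuple[Stage, float], ...]
    epoch_length_s: float = 30.0

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError("empty epoch")
        total = sum(d for _, d in self.labels)
        if abs(total - self.epoch_length_s) > 1e-9:
            raise ValueError(
                f"segment durations sum to {total} s, expected {self.epoch_length_s} s"
            )


def aggregate_epoch(
    annotation: SubEpochAnnotation, previous_stage: Optional[Stage] = None
) -> Stage:
    """Resolve a mixed epoch to a single stage by the >50% dominance rule.

    The stage whose summed duration strictly exceeds half the epoch wins.
    An exact 50/50 split has no dominant stage; the previous epoch's stage is
    carried forward. Without a previous stage, the stage with maximal duration
    is taken, ties broken toward the lighter stage.
    """
    totals: dict[Stage, float] = {}
    for stage, dur in annotation.labels:
        totals[stage] = totals.get(stage, 0.0) + dur
    half = annotation.epoch_length_s / 2.0
    for stage, dur in totals.items():
        if dur > half + 1e-12:
            return stage
    if previous_stage is not None:
        return previous_stage
    best = max(totals.items(), key=lambda kv: (kv[1], -kv[0].depth))
    return best[0]


@dataclass
class Hypnogram:
    """A staged recording for one animal.

    stages and phase are equal-length, non-empty sequences; every epoch has
    exactly one stage and one lights phase.
    """

    animal_id: str
    stages: tuple[Stage, ...]
    phase: tuple[Phase, ...]
    epoch_length_s: float = 30.0
    start_clock: Optional[str] = None

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        self.phase = tuple(self.phase)
        if len(self.stages) == 0:
            raise ValueError("hypnogram has no epochs")
        if len(self.stages) != len(self.phase):
            raise ValueError(
                f"stages ({len(self.stages)}) and phase ({len(self.phase)}) "
                "length mismatch"
            )
        if self.epoch_length_s <= 0:
            raise ValueError("epoch_length_s must be positive")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_h(self) -> float:
        return len(self.stages) * self.epoch_length_s / 3600.0

    def subset(self, indices: Sequence[int], suffix: str = "") -> "Hypnogram":
        idx = list(indices)
        return Hypnogram(
            animal_id=self.animal_id + suffix,
            stages=tuple(self.stages[i] for i in idx),
            phase=tuple(self.phase[i] for i in idx),
            epoch_length_s=self.epoch_length_s,
            start_clock=self.start_clock,
        )


HYPNOGRAM_COLUMNS = ["epoch_index", "start_time_s", "stage", "phase"]


def read_hypnogram(path, animal_id: Optional[str] = None,
                   epoch_length_s: float = 30.0) -> Hypnogram:
    """Read a hypnogram from UTF-8 CSV.

    Expected header: ``epoch_index,start_time_s,stage,phase`` (start_time_s
    optional). Unknown stage or phase strings are rejected with the offending
    row named.
    """
    df = pd.read_csv(path, dtype=str)
    if "stage" not in df.columns or "phase" not in df.columns:
        raise ValueError(f"{path}: missing required columns 'stage'/'phase'")
    if len(df) == 0:
        raise ValueError(f"{path}: empty hypnogram file")
    stages = []
    phases = []
    valid_stage = {s.value: s for s in Stage}
    valid_phase = {p.value: p for p in Phase}
    for row_no, (st, ph) in enumerate(zip(df["stage"], df["phase"])):
        if st not in valid_stage:
            raise ValueError(f"{path}: unknown stage label {st!r} at data row {row_no}")
        if ph not in valid_phase:
            raise ValueError(f"{path}: unknown phase label {ph!r} at data row {row_no}")
        stages.append(valid_stage[st])
        phases.append(valid_phase[ph])
    if animal_id is None:
        animal_id = str(df["animal_id"].iloc[0]) if "animal_id" in df.columns else "unknown"
    return Hypnogram(animal_id=animal_id, stages=tuple(stages), phase=tuple(phases),
                     epoch_length_s=epoch_length_s)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    """Write a hypnogram as CSV; ``read_hypnogram(write_hypnogram(h)) == h``."""
    df = pd.DataFrame(
        {
            "epoch_index": range(len(hyp)),
            "start_time_s": [i * hyp.epoch_length_s for i in range(len(hyp))],
            "stage": [s.value for s in hyp.stages],
            "phase": [p.value for p in hyp.phase],
            "animal_id": hyp.animal_id,
        }
    )
    df.to_csv(path, index=False)


def split_by_phase(hyp: Hypnogram) -> tuple[Hypnogram, Hypnogram]:
    """Split into (lights-on part, lights-off part), preserving epoch order.

    Either part may be empty (returned as None in that slot). Epoch boundaries
    that span a phase change belong to neither part; per-phase transition
    counts computed on the parts therefore exclude phase-boundary transitions,
    while counts on the full hypnogram include them.
    """
    on_idx = [i for i, p in enumerate(hyp.phase) if p is Phase.LIGHTS_ON]
    off_idx = [i for i, p in enumerate(hyp.phase) if p is Phase.LIGHTS_OFF]
    on = hyp.subset(on_idx) if on_idx else None
    off = hyp.subset(off_idx) if off_idx else None
    return on, off
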