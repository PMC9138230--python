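"""PTZ seizure-susceptibility test: event classification and session outcomes.

After an intraperitoneal pentylenetetrazol (PTZ) injection, a 60-min EEG
window is scored for three event classes distinguished purely by duration:

* spike: 20-70 ms (inclusive bounds),
* epileptiform discharge (ED): longer than 70 ms and shorter than 10 s,
* seizure: at least 10 s (boundary inclusive).

Durations below 20 ms are flagged ``unclassified`` rather than silently
dropped. Spikes occurring inside an ED or a seizure interval are excluded
from the spike count (they belong to the larger event).

The per-session outcome holds the latency to the first event of each class
(missing — never 0 — when the class is absent), counts per class, individual
seizure durations, and the Racine score of the first seizure if annotated.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "EventClass",
    "EEGEvent",
    "PTZSessionOutcome",
    "classify_event",
    "exclude_nested_spikes",
    "ptz_outcomes",
    "percent_seizing",
    "read_events",
    "outcome_frame",
]

SPIKE_MIN_S = 0.020
SPIKE_MAX_S = 0.070
SEIZURE_MIN_S = 10.0
DEFAULT_WINDOW_S = 3600.0


class EventClass(enum.Enum):
    SPIKE = "spike"
    EPILEPTIFORM_DISCHARGE = "epileptiform_discharge"
    SEIZURE = "seizure"
    UNCLASSIFIED = "unclassified"


def classify_event(duration_s: float) -> EventClass:
    """Assign the duration-rule class; positive durations partition exactly."""
    if duration_s <= 0:
        raise ValueError(f"nonpositive event duration {duration_s}")
    if duration_s < SPIKE_MIN_S:
        return EventClass.UNCLASSIFIED
    if duration_s <= SPIKE_MAX_S:
        return EventClass.SPIKE
    if duration_s < SEIZURE_MIN_S:
        return EventClass.EPILEPTIFORM_DISCHARGE
    return EventClass.SEIZURE


@dataclass(frozen=True)
class EEGEvent:
    onset_s: float
    duration_s: float
    racine: Optional[int] = None
    event_class: EventClass = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.event_class is None:
            object.__setattr__(self, "event_class", classify_event(self.duration_s))
        if self.racine is not None and not 0 <= self.racine <= 5:
            raise ValueError("racine score must be in 0..5")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s

    def overlaps(self, other: "EEGEvent") -> bool:
        # half-open intervals [onset, end)
        return self.onset_s < other.end_s and other.onset_s < self.end_s


def exclude_nested_spikes(events: Sequence[EEGEvent]) -> list[EEGEvent]:
    """Drop spikes overlapping any ED or seizure interval; idempotent.

    Overlap is checked on half-open [onset, end) intervals against the merged
    union of ED/seizure intervals (sessions can hold >1000 spikes, so the
    check is interval-merge + bisect rather than pairwise).
    """
    import bisect

    big = sorted(
        (
            (e.onset_s, e.end_s)
            for e in events
            if e.event_class in (EventClass.EPILEPTIFORM_DISCHARGE, EventClass.SEIZURE)
        )
    )
    merged: list[tuple[float, float]] = []
    for lo, hi in big:
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    starts = [lo for lo, _ in merged]

    def hits(e: EEGEvent) -> bool:
        # candidate: last merged interval starting before the spike ends
        j = bisect.bisect_left(starts, e.end_s) - 1
        return j >= 0 and merged[j][1] > e.onset_s

    return [
        e
        for e in events
        if not (e.event_class is EventClass.SPIKE and hits(e))
    ]


@dataclass
class PTZSessionOutcome:
    """The nine outcome measures for one animal on one testing day."""

    animal_id: str
    day: int
    latency_first_spike_s: Optional[float] = None
    latency_first_ed_s: Optional[float] = None
    latency_first_seizure_s: Optional[float] = None
    n_spikes: int = 0
    n_eds: int = 0
    n_seizures: int = 0
    seizure_durations_s: list[float] = field(default_factory=list)
    first_seizure_racine: Optional[int] = None
    window_s: float = DEFAULT_WINDOW_S

    def __post_init__(self) -> None:
        if self.n_seizures != len(self.seizure_durations_s):
            raise ValueError("n_seizures must equal len(seizure_durations_s)")


def ptz_outcomes(
    events: Sequence[EEGEvent],
    animal_id: str = "unknown",
    day: int = 0,
    window_s: float = DEFAULT_WINDOW_S,
) -> PTZSessionOutcome:
    """Extract the session outcome from classified events.

    Events with onset at or beyond the analysis window are excluded. Spike
    counting runs after nested-spike exclusion; latencies are minimal onsets
    per class, missing when the class is absent.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    inside = [e for e in events if e.onset_s < window_s]
    kept = exclude_nested_spikes(inside)

    def first_onset(cls: EventClass) -> Optional[float]:
        onsets = [e.onset_s for e in kept if e.event_class is cls]
        return min(onsets) if onsets else None

    seizures = sorted(
        (e for e in kept if e.event_class is EventClass.SEIZURE),
        key=lambda e: e.onset_s,
    )
    return PTZSessionOutcome(
        animal_id=animal_id,
        day=day,
        latency_first_spike_s=first_onset(EventClass.SPIKE),
        latency_first_ed_s=first_onset(EventClass.EPILEPTIFORM_DISCHARGE),
        latency_first_seizure_s=seizures[0].onset_s if seizures else None,
        n_spikes=sum(1 for e in kept if e.event_class is EventClass.SPIKE),
        n_eds=sum(1 for e in kept if e.event_class is EventClass.EPILEPTIFORM_DISCHARGE),
        n_seizures=len(seizures),
        seizure_durations_s=[e.duration_s for e in seizures],
        first_seizure_racine=seizures[0].racine if seizures else None,
        window_s=window_s,
    )


def percent_seizing(sessions: Iterable[PTZSessionOutcome], day: int) -> float:
    """Percentage of animals tested on `day` with at least one seizure.

    The denominator is the number of animals tested that day (it may vary
    between days).
    """
    tested = [s for s in sessions if s.day == day]
    if not tested:
        raise ValueError(f"no sessions for day {day}")
    seizing = sum(1 for s in tested if s.n_seizures >= 1)
    return 100.0 * seizing / len(tested)


def read_events(path) -> pd.DataFrame:
    """Read an event table CSV: animal_id,day,onset_s,duration_s[,racine]."""
    df = pd.read_csv(path)
    required = {"animal_id", "day", "onset_s", "duration_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def outcome_frame(outcomes: Iterable[PTZSessionOutcome]) -> pd.DataFrame:
    """One row per (animal, day); missing latencies are NaN, never zero."""
    rows = []
    for o in outcomes:
        rows.append(
            {
                "animal_id": o.animal_id,
                "day": o.day,
                "latency_first_spike_s": _na(o.latency_first_spike_s),
                "latency_first_ed_s": _na(o.latency_first_ed_s),
                "latency_first_seizure_s": _na(o.latency_first_seizure_s),
                "n_spikes": o.n_spikes,
                "n_eds": o.n_eds,
                "n_seizures": o.n_seizures,
                "duration_first_seizure_s": _na(
                    o.seizure_durations_s[0] if o.seizure_durations_s else None
                ),
                "first_seizure_racine": _na(o.first_seizure_racine),
            }
        )
    return pd.DataFrame(rows)


def _na(v):
    return math.nan if v is None else v
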