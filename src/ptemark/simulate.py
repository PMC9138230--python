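"""Synthetic cohort generator with the statistical structure the analysis assumes.

Sleep is modelled as a first-order Markov chain over {W, N2, N3, REM} at
30-s epoch resolution with separate transition matrices for the lights-on
(rest) and lights-off (active) phases of a 12 h / 12 h cycle. The base
(sham) matrices are calibrated to realistic rodent sleep architecture:
~75% sleep during lights-on, ~46% during lights-off, wake bouts of several
minutes, short N2 bouts, N3 as the dominant sleep stage, and REM cycling
predominantly back to N3. Injury effects are applied as propensity
multipliers: TBI scales all transition (off-diagonal) propensities up and
shortens REM bouts; animals with epileptiform activity (e+) additionally
double the N3->W propensity. Rows are renormalized after scaling.

PTZ test outcomes are simulated at the event level — spike/ED/seizure event
lists with day-dependent seizure probability (rising over testing days in
the TBI group) and day-dependent latency distributions — and the outcome
measures are then extracted through the same classification pipeline used
for real event tables, so the generator never writes a feature directly.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .hypnogram import Hypnogram, Phase, Stage, STAGES
from .ptz import EEGEvent, PTZSessionOutcome, classify_event, ptz_outcomes
from .sleep import sleep_metrics_record, SleepMetricsRecord

__all__ = [
    "SleepGenParams",
    "PTZGenParams",
    "CohortConfig",
    "make_transition_matrices",
    "simulate_hypnogram",
    "simulate_ptz_events",
    "simulate_ptz_outcomes",
    "simulate_cohort",
    "FEATURE_LETTERS",
    "SLEEP_FEATURES",
]

# Base stochastic matrices, rows/cols ordered W, N2, N3, REM.
# Lights-on: rest phase, ~75% sleep.
_BASE_ON = np.array(
    [
        [0.940, 0.048, 0.009, 0.003],
        [0.030, 0.700, 0.250, 0.020],
        [0.015, 0.025, 0.880, 0.080],
        [0.040, 0.040, 0.140, 0.780],
    ]
)
# Lights-off: active phase, ~46% sleep, long wake bouts.
_BASE_OFF = np.array(
    [
        [0.9700, 0.0240, 0.0045, 0.0015],
        [0.060, 0.570, 0.350, 0.020],
        [0.025, 0.030, 0.860, 0.085],
        [0.070, 0.040, 0.150, 0.740],
    ]
)

DAYS = (30, 60, 90, 180)


@dataclass(frozen=True)
class SleepGenParams:
    """Markov sleep-architecture parameters.

    tbi_transition_mult scales every off-diagonal entry for injured animals
    (>1 raises transition propensity, hence SFI); tbi_rem_stay_delta is
    subtracted from the REM self-transition before scaling (shorter REM
    bouts); eplus_n3_wake_mult additionally scales the N3->W entry for
    animals with epileptiform activity (the direction seen in epilepsy-prone
    animals).
    """

    base_on: np.ndarray = field(default_factory=lambda: _BASE_ON.copy())
    base_off: np.ndarray = field(default_factory=lambda: _BASE_OFF.copy())
    tbi_transition_mult: float = 1.25
    tbi_rem_stay_delta: float = 0.04
    eplus_n3_wake_mult: float = 2.0
    # between-animal heterogeneity: per-animal lognormal multiplier (sd on the
    # log scale) applied to all transition propensities in simulate_cohort;
    # 0.16 reproduces the reported between-animal spread of the fragmentation
    # index (group SEM ~0.8 at n~11 -> SD ~2.7 around a mean of ~16/h)
    animal_jitter_sd: float = 0.16

    def __post_init__(self) -> None:
        for m in (self.base_on, self.base_off):
            _check_stochastic(m)
        if self.tbi_transition_mult <= 0 or self.eplus_n3_wake_mult <= 0:
            raise ValueError("multipliers must be positive")


def _check_stochastic(m: np.ndarray) -> None:
    m = np.asarray(m, float)
    if m.shape != (4, 4) or np.any(m < 0) or not np.allclose(m.sum(axis=1), 1.0):
        raise ValueError("base matrix must be 4x4 row-stochastic")


def make_transition_matrices(
    params: SleepGenParams, group: str, subgroup: Optional[str] = None
) -> dict[Phase, np.ndarray]:
    """Per-phase matrices for one animal; sham matrices pass through unchanged.

    group is 'sham' or 'tbi'; subgroup 'eplus'/'eminus' applies only to TBI.
    Off-diagonal entries are scaled, then each row is renormalized to sum 1.
    """
    if group not in ("sham", "tbi"):
        raise ValueError(f"unknown group {group!r}")
    out = {}
    for phase, base in ((Phase.LIGHTS_ON, params.base_on), (Phase.LIGHTS_OFF, params.base_off)):
        m = np.asarray(base, float).copy()
        if group == "tbi":
            # shorten REM bouts: move stay mass onto the existing exit profile
            i_rem = STAGES.index(Stage.REM)
            off = m[i_rem].copy()
            off[i_rem] = 0.0
            exit_p = off.sum()
            m[i_rem] = off * (exit_p + params.tbi_rem_stay_delta) / exit_p
            m[i_rem, i_rem] = 1.0 - (exit_p + params.tbi_rem_stay_delta)
            # raise every transition propensity
            mult = np.full((4, 4), params.tbi_transition_mult)
            np.fill_diagonal(mult, 1.0)
            m = m * mult
            if subgroup == "eplus":
                m[STAGES.index(Stage.N3), STAGES.index(Stage.W)] *= params.eplus_n3_wake_mult
        m = m / m.sum(axis=1, keepdims=True)
        out[phase] = m
    return out


def _scale_offdiag(m: np.ndarray, factor: float) -> np.ndarray:
    """Scale all off-diagonal entries by `factor` and renormalize rows."""
    mult = np.full((4, 4), factor)
    np.fill_diagonal(mult, 1.0)
    out = m * mult
    return out / out.sum(axis=1, keepdims=True)


def stationary_distribution(m: np.ndarray) -> np.ndarray:
    """Stationary row vector of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(m.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def expected_sfi(m: np.ndarray, epoch_length_s: float = 30.0) -> float:
    """Analytic transitions/hour of the stationary chain: (3600/L)(1 - sum pi_i P_ii)."""
    pi = stationary_distribution(m)
    return (3600.0 / epoch_length_s) * (1.0 - float(np.sum(pi * np.diag(m))))


def simulate_hypnogram(
    matrices: dict[Phase, np.ndarray],
    epochs_per_phase: tuple[int, int] = (1440, 1440),
    seed: int | np.random.Generator = 0,
    animal_id: str = "sim",
    epoch_length_s: float = 30.0,
    start_stage: Optional[Stage] = None,
) -> Hypnogram:
    """First-order Markov sampling: lights-on block then lights-off block.

    The initial stage is drawn from the stationary distribution of the
    lights-on matrix unless given; deterministic under a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_on, n_off = epochs_per_phase
    plan = [(Phase.LIGHTS_ON, n_on), (Phase.LIGHTS_OFF, n_off)]
    stages: list[Stage] = []
    phases: list[Phase] = []
    if start_stage is None:
        pi = stationary_distribution(matrices[Phase.LIGHTS_ON if n_on else Phase.LIGHTS_OFF])
        state = int(rng.choice(4, p=pi))
    else:
        state = STAGES.index(start_stage)
    for phase, n in plan:
        if n == 0:
            continue
        cum = np.cumsum(matrices[phase], axis=1)
        u = rng.random(n)
        for i in range(n):
            state = int(np.searchsorted(cum[state], u[i], side="right"))
            state = min(state, 3)
            stages.append(STAGES[state])
            phases.append(phase)
    return Hypnogram(
        animal_id=animal_id,
        stages=tuple(stages),
        phase=tuple(phases),
        epoch_length_s=epoch_length_s,
    )


# ---------------------------------------------------------------------------
# PTZ outcomes
# ---------------------------------------------------------------------------

def _lognormal_ms(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Lognormal draw parameterized by its arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


def _negbin(rng: np.random.Generator, mean: float, r: float) -> int:
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


@dataclass(frozen=True)
class PTZGenParams:
    """Per-day PTZ event-generation parameters for one treatment group.

    seizure_p: probability of at least one seizure per testing day (rising
    over days in TBI animals). Latency means/SDs are in seconds; counts are
    negative-binomial with the given dispersion r. eplus_latency_mult scales
    ED/seizure latencies for e+ (<1) and e- (>1) subgroups.
    """

    seizure_p: dict[int, float]
    ed_latency_mean: dict[int, float]
    ed_latency_sd: dict[int, float]
    seizure_latency_mean: dict[int, float]
    seizure_latency_sd: dict[int, float]
    extra_seizures_mean: dict[int, float]
    spike_count_mean: float = 1400.0
    spike_count_r: float = 4.0
    ed_count_mean: float = 170.0
    ed_count_r: float = 2.0
    spike_latency_mean: float = 200.0
    spike_latency_sd: float = 250.0
    seizure_duration_mean_s: float = 55.0
    seizure_duration_sd_s: float = 45.0
    eplus_latency_mult: float = 0.85
    eminus_latency_mult: float = 1.25
    # e+ animals are more susceptible: more PTZ-induced seizures and EDs,
    # e- animals fewer (odds-scaling on seizure_p, multiplicative on counts)
    eplus_seizure_odds_mult: float = 1.6
    eminus_seizure_odds_mult: float = 0.6
    eplus_count_mult: float = 1.3
    eminus_count_mult: float = 0.75
    window_s: float = 3600.0
    dose_mg_per_kg: float = 25.0  # 30 mg/kg appears in some summaries; session metadata only

    def __post_init__(self) -> None:
        for d, p in self.seizure_p.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"seizure_p[{d}]={p} outside [0, 1]")


def default_ptz_params(group: str) -> PTZGenParams:
    """Day-dependent defaults reflecting the studied cohorts' trends."""
    if group == "sham":
        return PTZGenParams(
            seizure_p={30: 0.31, 60: 0.31, 90: 0.44, 180: 0.56},
            ed_latency_mean={30: 316, 60: 205, 90: 359, 180: 239},
            ed_latency_sd={30: 388, 60: 341, 90: 546, 180: 230},
            seizure_latency_mean={30: 1192, 60: 197, 90: 658, 180: 588},
            seizure_latency_sd={30: 1374, 60: 84, 90: 1168, 180: 853},
            extra_seizures_mean={30: 0.0, 60: 0.2, 90: 0.0, 180: 0.9},
        )
    if group == "tbi":
        return PTZGenParams(
            seizure_p={30: 0.15, 60: 0.43, 90: 0.54, 180: 0.59},
            ed_latency_mean={30: 480, 60: 311, 90: 176, 180: 227},
            ed_latency_sd={30: 662, 60: 422, 90: 138, 180: 180},
            seizure_latency_mean={30: 370, 60: 276, 90: 177, 180: 326},
            seizure_latency_sd={30: 209, 60: 148, 90: 93, 180: 287},
            extra_seizures_mean={30: 0.3, 60: 0.4, 90: 0.5, 180: 0.95},
        )
    raise ValueError(f"unknown group {group!r}")


def simulate_ptz_events(
    params: PTZGenParams,
    day: int,
    rng: np.random.Generator,
    subgroup: Optional[str] = None,
) -> list[EEGEvent]:
    """Event list (spikes, EDs, seizures) for one animal-day session."""
    w = params.window_s
    lat_mult = {
        "eplus": params.eplus_latency_mult,
        "eminus": params.eminus_latency_mult,
        None: 1.0,
    }[subgroup]
    odds_mult = {
        "eplus": params.eplus_seizure_odds_mult,
        "eminus": params.eminus_seizure_odds_mult,
        None: 1.0,
    }[subgroup]
    count_mult = {
        "eplus": params.eplus_count_mult,
        "eminus": params.eminus_count_mult,
        None: 1.0,
    }[subgroup]
    p_base = params.seizure_p[day]
    if 0.0 < p_base < 1.0:
        odds = odds_mult * p_base / (1.0 - p_base)
        p_seiz = odds / (1.0 + odds)
    else:
        p_seiz = p_base
    events: list[EEGEvent] = []

    # seizures
    if rng.random() < p_seiz:
        n_seiz = 1 + int(rng.poisson(params.extra_seizures_mean[day]))
        first = min(
            _lognormal_ms(rng, params.seizure_latency_mean[day],
                          params.seizure_latency_sd[day]) * lat_mult,
            w * 0.95,
        )
        onsets = [first] + list(rng.uniform(first, w, size=n_seiz - 1))
        for t in onsets:
            dur = 10.0 + _lognormal_ms(
                rng, params.seizure_duration_mean_s - 10.0, params.seizure_duration_sd_s
            )
            events.append(
                EEGEvent(onset_s=float(t), duration_s=float(dur),
                         racine=int(rng.integers(3, 6)))
            )

    # epileptiform discharges
    n_ed = max(1, _negbin(rng, params.ed_count_mean * count_mult, params.ed_count_r))
    first_ed = min(
        _lognormal_ms(rng, params.ed_latency_mean[day], params.ed_latency_sd[day]) * lat_mult,
        w * 0.95,
    )
    ed_onsets = np.concatenate([[first_ed], rng.uniform(first_ed, w, size=n_ed - 1)])
    ed_durs = rng.uniform(0.2, 8.0, size=n_ed)
    for t, d in zip(ed_onsets, ed_durs):
        events.append(EEGEvent(onset_s=float(t), duration_s=float(d)))

    # spikes
    n_sp = max(1, _negbin(rng, params.spike_count_mean, params.spike_count_r))
    first_sp = min(
        _lognormal_ms(rng, params.spike_latency_mean, params.spike_latency_sd), w * 0.9
    )
    sp_onsets = np.concatenate([[first_sp], rng.uniform(first_sp, w, size=n_sp - 1)])
    sp_durs = rng.uniform(0.020, 0.070, size=n_sp)
    for t, d in zip(sp_onsets, sp_durs):
        events.append(EEGEvent(onset_s=float(t), duration_s=float(d)))

    events.sort(key=lambda e: e.onset_s)
    return events


def simulate_ptz_outcomes(
    params: PTZGenParams,
    days: Sequence[int] = DAYS,
    seed: int | np.random.Generator = 0,
    animal_id: str = "sim",
    subgroup: Optional[str] = None,
) -> list[PTZSessionOutcome]:
    """Per-day outcomes, extracted from simulated events by the session pipeline."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for day in days:
        events = simulate_ptz_events(params, day, rng, subgroup=subgroup)
        out.append(ptz_outcomes(events, animal_id=animal_id, day=day,
                                window_s=params.window_s))
    return out


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

# Table-5-style feature letters: A-E per PTZ testing day, F-M from sleep.
FEATURE_LETTERS = {
    "A": "latency_first_ed_s",
    "B": "n_eds",
    "C": "n_seizures",
    "D": "latency_first_seizure_s",
    "E": "duration_first_seizure_s",
}
SLEEP_FEATURES = {
    "F": ("mean_bout_min_REM", "off"),
    "G": ("transitions_to_N3", "on"),
    "H": ("total_transitions", "on"),
    "I": ("sfi_total", "on"),
    "J": ("mean_bout_min_REM", "combined"),
    "K": ("transitions_to_REM", "on"),
    "L": ("total_transitions", "combined"),
    "M": ("sfi_total", "combined"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-structure defaults: 16 sham / 28 TBI, 15 e+ of whom 4 develop PTE."""

    n_sham: int = 16
    n_tbi: int = 28
    n_eplus: int = 15
    n_pte: int = 4
    epochs_per_phase: tuple[int, int] = (1440, 1440)
    days: tuple[int, ...] = DAYS
    sleep: SleepGenParams = field(default_factory=SleepGenParams)

    def __post_init__(self) -> None:
        if self.n_pte > self.n_eplus:
            raise ValueError("PTE+ animals are a subset of e+ animals")
        if self.n_eplus > self.n_tbi:
            raise ValueError("n_eplus cannot exceed n_tbi")


def _sleep_feature_row(rec: SleepMetricsRecord) -> dict[str, float]:
    from .sleep import metrics_frame

    df = metrics_frame([rec]).set_index("phase")
    return {
        letter: float(df.loc[phase, col])
        for letter, (col, phase) in SLEEP_FEATURES.items()
    }


def simulate_cohort(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    hypnogram_dir=None,
) -> pd.DataFrame:
    """Generate a fully labelled cohort table.

    One master seed spawns independent per-animal substreams. The generator
    writes raw hypnograms and event lists and extracts every feature through
    the sleep-metrics and PTZ-session pipelines; it never writes a feature
    value directly. If hypnogram_dir is given, per-animal hypnogram CSVs are
    written there.
    """
    from .hypnogram import write_hypnogram

    ss = np.random.SeedSequence(seed)
    n_total = config.n_sham + config.n_tbi
    streams = [np.random.default_rng(s) for s in ss.spawn(n_total)]

    rows = []
    for k in range(n_total):
        rng = streams[k]
        is_tbi = k >= config.n_sham
        group = "tbi" if is_tbi else "sham"
        if is_tbi:
            j = k - config.n_sham
            eplus = j < config.n_eplus
            pte = j < config.n_pte  # PTE+ subset of e+
            subgroup = "eplus" if eplus else "eminus"
        else:
            eplus = pte = None
            subgroup = None
        animal_id = f"{group}_{k:03d}"

        mats = make_transition_matrices(config.sleep, group, subgroup)
        if config.sleep.animal_jitter_sd > 0:
            factor = float(np.exp(rng.normal(0.0, config.sleep.animal_jitter_sd)))
            mats = {ph: _scale_offdiag(m, factor) for ph, m in mats.items()}
        hyp = simulate_hypnogram(
            mats, config.epochs_per_phase, seed=rng, animal_id=animal_id
        )
        if hypnogram_dir is not None:
            write_hypnogram(hyp, f"{hypnogram_dir}/{animal_id}.csv")
        rec = sleep_metrics_record(hyp)

        ptz_params = default_ptz_params(group)
        outcomes = simulate_ptz_outcomes(
            ptz_params, config.days, seed=rng, animal_id=animal_id, subgroup=subgroup
        )

        row: dict = {
            "animal_id": animal_id,
            "group": group,
            "is_tbi": int(is_tbi),
            "eplus": eplus if eplus is None else int(eplus),
            "pte": pte if pte is None else int(pte),
            "seed": seed,
        }
        row.update(_sleep_feature_row(rec))
        from .ptz import outcome_frame

        of = outcome_frame(outcomes).set_index("day")
        for day in config.days:
            row[f"A_d{day}"] = of.loc[day, "latency_first_ed_s"]
            row[f"B_d{day}"] = of.loc[day, "n_eds"]
            row[f"C_d{day}"] = of.loc[day, "n_seizures"]
            row[f"D_d{day}"] = of.loc[day, "latency_first_seizure_s"]
            row[f"E_d{day}"] = of.loc[day, "duration_first_seizure_s"]
        rows.append(row)
    return pd.DataFrame(rows)
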