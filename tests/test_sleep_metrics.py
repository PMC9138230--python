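import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ptemark.hypnogram import Hypnogram, Phase, Stage, write_hypnogram, read_hypnogram
from ptemark.sleep import (
    DEEP_TO_LIGHT_PAIRS,
    bouts,
    deep_to_light_counts,
    mean_bout_duration,
    metrics_frame,
    sfi,
    sleep_metrics_record,
    stage_durations,
    transition_summary,
)
from conftest import make_hyp


stage_seq = st.lists(st.integers(0, 3), min_size=1, max_size=200).map(
    lambda xs: " ".join(list(Stage)[i].name for i in xs)
)


class TestStageDurations:
    def test_hand_example(self):
        d = stage_durations(make_hyp("W W N2 N3"))
        assert d[Stage.W] == pytest.approx(1 / 60)
        assert d[Stage.N2] == pytest.approx(1 / 120)
        assert d[Stage.N3] == pytest.approx(1 / 120)
        assert d[Stage.REM] == 0.0

    def test_all_rem_24h(self):
        d = stage_durations(make_hyp(" ".join(["REM"] * 2880)))
        assert d[Stage.REM] == pytest.approx(24.0)

    def test_conservation_on_random_hypnogram(self, random_hypnogram):
        d = stage_durations(random_hypnogram)
        assert sum(d.values()) == pytest.approx(random_hypnogram.duration_h, abs=1e-9)


class TestBouts:
    def test_hand_example(self):
        got = bouts(make_hyp("N3 N3 REM W W W"))
        assert got == [(Stage.N3, 0, 2), (Stage.REM, 2, 1), (Stage.W, 3, 3)]

    def test_single_stage_is_one_bout(self):
        assert bouts(make_hyp("N2 N2 N2")) == [(Stage.N2, 0, 3)]

    @given(stage_seq)
    @settings(deadline=None)
    def test_bout_count_is_one_plus_stage_changes(self, seq):
        h = make_hyp(seq)
        n_changes = transition_summary(h).total
        assert len(bouts(h)) == 1 + n_changes

    @given(stage_seq)
    @settings(deadline=None)
    def test_bouts_partition_sequence(self, seq):
        h = make_hyp(seq)
        bs = bouts(h)
        assert sum(ln for _, _, ln in bs) == len(h)
        for (s1, _, _), (s2, _, _) in zip(bs, bs[1:]):
            assert s1 is not s2


class TestMeanBoutDuration:
    def test_hand_example(self):
        # REM runs of 2 and 1 epochs: (3 * 0.5 min) / 2 bouts
        assert mean_bout_duration(make_hyp("REM REM W REM"), Stage.REM) == pytest.approx(0.75)

    def test_single_bout(self):
        assert mean_bout_duration(make_hyp("N3 N3 N3 N3"), Stage.N3) == pytest.approx(2.0)

    def test_absent_stage_is_missing_not_zero(self):
        assert mean_bout_duration(make_hyp("W W"), Stage.REM) is None


class TestTransitions:
    def test_hand_count(self):
        ts = transition_summary(make_hyp("W N2 N3 N3 REM W"))
        assert ts.total == 4
        assert ts.counts[0, 1] == 1  # W -> N2
        assert ts.counts[1, 2] == 1  # N2 -> N3
        assert ts.counts[2, 3] == 1  # N3 -> REM
        assert ts.counts[3, 0] == 1  # REM -> W

    def test_constant_hypnogram_all_zero(self):
        ts = transition_summary(make_hyp(" ".join(["N3"] * 50)))
        assert ts.total == 0

    def test_phase_boundary_transition_skipped_when_respected(self):
        h = make_hyp("W W N2 N2", phase="n n f f")
        assert transition_summary(h, respect_phase_boundaries=True).total == 0
        assert transition_summary(h, respect_phase_boundaries=False).total == 1

    @given(stage_seq)
    @settings(deadline=None)
    def test_total_equals_row_and_column_sums(self, seq):
        ts = transition_summary(make_hyp(seq))
        assert ts.total == sum(ts.transitions_to(s) for s in Stage)
        assert ts.total == sum(ts.transitions_from(s) for s in Stage)

    @given(stage_seq)
    @settings(deadline=None)
    def test_bouts_of_stage_equal_entries_plus_initial(self, seq):
        h = make_hyp(seq)
        ts = transition_summary(h)
        for s in Stage:
            n_bouts = sum(1 for b, _, _ in bouts(h) if b is s)
            assert n_bouts == ts.transitions_to(s) + (1 if h.stages[0] is s else 0)


class TestDeepToLight:
    def test_exactly_six_ordered_pairs(self):
        assert len(DEEP_TO_LIGHT_PAIRS) == 6
        for a, b in DEEP_TO_LIGHT_PAIRS:
            assert b.depth < a.depth

    def test_hand_count(self):
        ts = transition_summary(make_hyp("W N2 N3 REM N3 N2 W"))
        d2l = deep_to_light_counts(ts)
        assert sum(d2l.values()) == 3  # REM->N3, N3->N2, N2->W
        assert d2l[(Stage.REM, Stage.N3)] == 1
        assert d2l[(Stage.N3, Stage.N2)] == 1
        assert d2l[(Stage.N2, Stage.W)] == 1

    @given(stage_seq)
    @settings(deadline=None)
    def test_deep_to_light_subset_of_total(self, seq):
        ts = transition_summary(make_hyp(seq))
        assert 0 <= sum(deep_to_light_counts(ts).values()) <= ts.total


class TestSFI:
    def test_four_transitions_over_two_hours(self):
        h = make_hyp("W N2 W N2 W " + "W " * 235)  # 240 epochs = 2 h
        ts = transition_summary(h)
        assert ts.total == 4
        assert sfi(ts)[0] == pytest.approx(2.0)

    def test_constant_hypnogram_zero_rate(self):
        total, d2l = sfi(transition_summary(make_hyp("N3 " * 120)))
        assert total == 0.0 and d2l == 0.0

    def test_sfi_total_bounds(self, random_hypnogram):
        ts = transition_summary(random_hypnogram)
        total, d2l = sfi(ts)
        assert total >= d2l >= 0.0
        assert total <= (len(random_hypnogram) - 1) / random_hypnogram.duration_h

    def test_two_state_markov_matches_analytic_rate(self):
        # stay-probability 0.9: expected 120 * 0.1 = 12 transitions/hour
        rng = np.random.default_rng(7)
        n = 30_000
        states = np.empty(n, dtype=int)
        states[0] = 0
        flips = rng.random(n - 1) > 0.9
        states[1:] = np.where(flips, 1, 0)
        states = np.logical_xor.accumulate(np.concatenate([[0], flips])).astype(int)
        stages = tuple(Stage.W if s == 0 else Stage.N3 for s in states)
        h = Hypnogram(animal_id="m", stages=stages,
                      phase=tuple(Phase.LIGHTS_ON for _ in stages))
        total, _ = sfi(transition_summary(h))
        assert total == pytest.approx(12.0, rel=0.05)


class TestSleepMetricsRecord:
    def test_all_wake(self):
        rec = sleep_metrics_record(make_hyp("W " * 10, phase="n " * 5 + "f " * 5))
        assert rec.sleep_h["combined"] == 0.0
        assert rec.sfi_total["combined"] == 0.0

    def test_record_invariants(self, random_hypnogram):
        rec = sleep_metrics_record(random_hypnogram)
        for key in ("on", "off", "combined"):
            assert rec.sleep_h[key] + rec.wake_h[key] == pytest.approx(
                rec.duration_h[key], abs=1e-9
            )
            assert rec.total_transitions[key] == sum(rec.transitions_to[key].values())
            assert rec.sfi_total[key] == pytest.approx(
                rec.total_transitions[key] / rec.duration_h[key]
            )

    def test_round_trip_recomputation_identical(self, tmp_path, random_hypnogram):
        rec1 = sleep_metrics_record(random_hypnogram)
        p = tmp_path / "h.csv"
        write_hypnogram(random_hypnogram, p)
        rec2 = sleep_metrics_record(read_hypnogram(p))
        assert metrics_frame([rec1]).equals(metrics_frame([rec2]))

    def test_combined_includes_phase_boundary_transition(self):
        # W..W | N2..N2 : per-phase counts 0, combined counts 1
        h = make_hyp("W W N2 N2", phase="n n f f")
        rec = sleep_metrics_record(h)
        assert rec.total_transitions["on"] == 0
        assert rec.total_transitions["off"] == 0
        assert rec.total_transitions["combined"] == 1
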