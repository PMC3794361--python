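"""Phase controllers: habituation, magazine, stimulus-light, 5-CSRTT."""

import numpy as np
import pytest

from conftest import make_entry_events
from fishrig.detect import DetectionEvent
from fishrig.session import (
    CommandKind,
    Outcome,
    Phase,
    SessionSchedule,
    drive_apparatus,
    run_5csrtt_session,
    run_habituation,
    run_magazine_training,
    run_stimulus_light_training,
    select_stimulus,
)

FPS = 50.0


def sched(phase, **kw):
    return SessionSchedule(phase=phase, **kw)


class TestHabituation:
    def test_rate_limited_deliveries(self):
        events = make_entry_events({"magazine": [5.0, 10.0, 40.0]})
        log = run_habituation(sched(Phase.HABITUATION), events)
        feeds = [c.time_s for c in log.commands if c.kind is CommandKind.FEED]
        assert feeds == [5.0, 40.0]

    def test_no_entries_no_deliveries(self):
        log = run_habituation(sched(Phase.HABITUATION), [])
        assert log.n_reinforcers == 0

    def test_entry_every_second_gives_four_deliveries(self):
        # entries at 1..120 s: deliveries at 1, 31, 61, 91
        events = make_entry_events({"magazine": [float(t) for t in range(1, 121)]})
        log = run_habituation(sched(Phase.HABITUATION), events)
        assert log.n_reinforcers == 4


class TestMagazineTraining:
    def test_entry_each_illumination_cycle_arithmetic(self):
        # settling gap 30 s, entry 3 s after each light-on: 33-s cycles,
        # deliveries at 33, 66, ..., 1782 -> 54 in an 1800-s session
        entries = [30.0 + 33.0 * k + 3.0 for k in range(60)]
        events = make_entry_events({"magazine": entries})
        log = run_magazine_training(sched(Phase.MAGAZINE), events)
        assert log.n_reinforcers == 54

    def test_no_entries_cycle_length_40(self):
        log = run_magazine_training(sched(Phase.MAGAZINE), [])
        assert log.n_reinforcers == 0
        ons = [c.time_s for c in log.commands if c.kind is CommandKind.MAG_LED_ON]
        assert ons[:3] == [30.0, 70.0, 110.0]  # 10-s light + 30-s gap

    def test_entry_during_gap_only(self):
        # first light at 30; entries land in dark gaps only
        events = make_entry_events({"magazine": [15.0, 45.0]})
        log = run_magazine_training(sched(Phase.MAGAZINE), events)
        assert log.n_reinforcers == 0


class TestStimulusLightTraining:
    def test_single_cycle(self):
        events = make_entry_events({"aperture_3": [70.0], "magazine": [80.0]})
        log = run_stimulus_light_training(sched(Phase.STIMULUS_LIGHT), events)
        assert log.n_reinforcers == 1
        feeds = [c for c in log.commands if c.kind is CommandKind.FEED]
        assert [c.time_s for c in feeds] == [80.0]

    def test_no_aperture_entries(self):
        log = run_stimulus_light_training(sched(Phase.STIMULUS_LIGHT), [])
        assert log.n_reinforcers == 0

    def test_three_full_cycles(self):
        # cycle: gate up -> aperture -> magazine (feed) -> 20-s pause
        events = make_entry_events(
            {"aperture_1": [70.0, 110.0, 140.0], "magazine": [80.0, 115.0, 150.0]},
        )
        log = run_stimulus_light_training(
            sched(Phase.STIMULUS_LIGHT, session_length_s=300.0), events
        )
        assert log.n_reinforcers == 3
        gate_ups = [c.time_s for c in log.commands if c.kind is CommandKind.GATE_UP]
        assert gate_ups[:3] == [60.0, 100.0, 135.0]


def build_5csrtt_stream(schedule: SessionSchedule, plan):
    """Hand-trace a scripted event stream realizing a plan of outcomes.

    ``plan`` items: ("C", latency), ("I", latency), ("A", delay_into_psi),
    ("O",).  Returns (events, expected outcome list).  Timing follows the
    protocol narrative directly: gate up, gate latency, PSI, stimulus
    window, timeout/ITI.
    """
    rng = np.random.default_rng(schedule.rng_seed)
    t0 = schedule.initial_hold_s
    times: dict[str, list[float]] = {}
    expected = []

    def add(region, t):
        times.setdefault(region, []).append(t)

    for item in plan:
        lit = select_stimulus(rng)
        t_open = t0 + schedule.gate_latency_s
        t_stim = t_open + schedule.psi_s
        kind = item[0]
        if kind == "A":
            t_r = t_open + item[1]
            assert item[1] < schedule.psi_s
            add("aperture_3", t_r)
            expected.append(Outcome.ANTICIPATORY)
            t0 = t_r + schedule.timeout_s
        elif kind == "C":
            t_r = t_stim + item[1]
            add(f"aperture_{lit}", t_r)
            t_m = t_r + 2.0
            add("magazine", t_m)
            expected.append(Outcome.CORRECT)
            t0 = t_m + schedule.iti_s
        elif kind == "I":
            wrong = lit % 5 + 1
            t_r = t_stim + item[1]
            add(f"aperture_{wrong}", t_r)
            expected.append(Outcome.INCORRECT)
            t0 = t_r + schedule.timeout_s
        elif kind == "O":
            expected.append(Outcome.OMISSION)
            t0 = t_stim + schedule.stimulus_duration_s + schedule.timeout_s
        else:
            raise ValueError(kind)
    return make_entry_events(times, fps=schedule.fps), expected


class TestFiveChoice:
    def schedule(self, **kw):
        kw.setdefault("session_length_s", 3600.0)
        kw.setdefault("rng_seed", 202)
        return sched(Phase.FIVE_CSRTT, **kw)

    def test_correct_entry_latency(self):
        schedule = self.schedule()
        events, _ = build_5csrtt_stream(schedule, [("C", 2.5)])
        log = run_5csrtt_session(schedule, events, max_trials=1)
        (tr,) = log.trials
        assert tr.outcome is Outcome.CORRECT
        assert tr.response_latency_s == pytest.approx(2.5)
        assert tr.responded_position == tr.stimulus_position

    def test_entry_during_psi_is_anticipatory(self):
        schedule = self.schedule()
        events, _ = build_5csrtt_stream(schedule, [("A", 4.0)])  # 1 s before onset
        log = run_5csrtt_session(schedule, events, max_trials=1)
        (tr,) = log.trials
        assert tr.outcome is Outcome.ANTICIPATORY
        assert tr.response_latency_s is None
        assert tr.t_stim_on is None

    def test_no_entry_is_omission(self):
        schedule = self.schedule()
        log = run_5csrtt_session(schedule, [])
        assert log.trials[0].outcome is Outcome.OMISSION

    def test_scripted_ten_trial_session(self):
        schedule = self.schedule()
        plan = [("C", 2.0), ("C", 3.0), ("I", 1.5), ("C", 4.0), ("A", 2.0),
                ("C", 2.5), ("O",), ("C", 1.0), ("I", 6.0), ("C", 5.0)]
        events, expected = build_5csrtt_stream(schedule, plan)
        log = run_5csrtt_session(schedule, events, max_trials=10)
        assert [t.outcome for t in log.trials] == expected
        counts = log.outcome_counts()
        assert counts[Outcome.CORRECT] == 6
        assert counts[Outcome.INCORRECT] == 2
        assert counts[Outcome.ANTICIPATORY] == 1
        assert counts[Outcome.OMISSION] == 1
        assert sum(counts.values()) == log.n_trials == 10

    def test_one_feed_per_correct_trial(self):
        schedule = self.schedule()
        plan = [("C", 2.0), ("I", 1.0), ("C", 3.0), ("O",), ("A", 1.0)]
        events, _ = build_5csrtt_stream(schedule, plan)
        log = run_5csrtt_session(schedule, events, max_trials=5)
        feeds = [c for c in log.commands if c.kind is CommandKind.FEED]
        assert len(feeds) == 2 == log.n_reinforcers

    def test_stimulus_led_only_lit_during_stimulus_window(self):
        schedule = self.schedule()
        plan = [("C", 2.0), ("A", 3.0), ("O",), ("I", 10.0)]
        events, _ = build_5csrtt_stream(schedule, plan)
        log = run_5csrtt_session(schedule, events, max_trials=4)
        led_on = {c.time_s for c in log.commands if c.kind is CommandKind.STIM_LED_ON}
        for tr in log.trials:
            if tr.outcome is Outcome.ANTICIPATORY:
                continue
            assert tr.t_stim_on in led_on
            # LED never lit during PSI and off by the end of the window
            assert tr.t_stim_on >= tr.t_psi_start + schedule.psi_s
            assert tr.t_stim_off <= tr.t_stim_on + schedule.stimulus_duration_s
        # anticipatory trials never light a stimulus LED
        n_led = len([c for c in log.commands if c.kind is CommandKind.STIM_LED_ON])
        assert n_led == sum(1 for t in log.trials if t.outcome is not Outcome.ANTICIPATORY)

    def test_fresh_onset_rule_ignores_preexisting_occupancy(self):
        # fish already inside an aperture before the gate opens: that onset
        # precedes the accessible window and must not count as a response
        schedule = self.schedule()
        ev = DetectionEvent("aperture_2", 2500, 4000, 50.0, 80.0)
        log = run_5csrtt_session(schedule, [ev], max_trials=1)
        assert log.trials[0].outcome is Outcome.OMISSION

    def test_out_of_order_events_rejected(self):
        schedule = self.schedule()
        events = [
            DetectionEvent("aperture_1", 5000, 5025, 100.0, 100.5),
            DetectionEvent("magazine", 4000, 4025, 80.0, 80.5),
        ]
        with pytest.raises(ValueError, match="out of time order"):
            run_5csrtt_session(schedule, events)

    def test_determinism_same_inputs_same_log(self):
        schedule = self.schedule()
        events, _ = build_5csrtt_stream(schedule, [("C", 2.0), ("I", 1.0), ("O",)])
        a = run_5csrtt_session(schedule, events, "f", 0)
        b = run_5csrtt_session(schedule, events, "f", 0)
        assert a.trials == b.trials and a.commands == b.commands

    def test_trial_in_progress_at_expiry_discarded(self):
        # session ends during the first stimulus window: nothing recorded
        schedule = self.schedule(session_length_s=80.0)
        log = run_5csrtt_session(schedule, [])
        assert log.trials == []


class TestSelectStimulus:
    def test_uniform_within_three_standard_errors(self):
        rng = np.random.default_rng(77)
        n = 5000
        draws = [select_stimulus(rng) for _ in range(n)]
        se = np.sqrt(0.2 * 0.8 / n)
        for pos in range(1, 6):
            assert abs(draws.count(pos) / n - 0.2) < 3 * se
        assert sum(draws.count(p) for p in range(1, 6)) == n

    def test_seed_reproducibility(self):
        r1, r2 = np.random.default_rng(9), np.random.default_rng(9)
        assert [select_stimulus(r1) for _ in range(100)] == [
            select_stimulus(r2) for _ in range(100)
        ]


class TestDriveApparatus:
    def make_log(self, plan, **kw):
        schedule = SessionSchedule(phase=Phase.FIVE_CSRTT, session_length_s=3600.0,
                                   rng_seed=11, **kw)
        events, _ = build_5csrtt_stream(schedule, plan)
        return run_5csrtt_session(schedule, events, max_trials=len(plan))

    def test_rebuild_matches_controller_commands(self):
        log = self.make_log([("C", 2.0), ("I", 1.0), ("A", 2.5), ("O",), ("C", 3.0)])
        assert drive_apparatus(log) == log.commands

    def test_three_correct_trials_three_feeds(self):
        log = self.make_log([("C", 2.0), ("C", 3.0), ("C", 4.0)])
        feeds = [c for c in drive_apparatus(log) if c.kind is CommandKind.FEED]
        assert len(feeds) == 3

    def test_omission_led_off_exactly_at_window_end(self):
        log = self.make_log([("O",)])
        cmds = drive_apparatus(log)
        on = next(c for c in cmds if c.kind is CommandKind.STIM_LED_ON)
        off = next(c for c in cmds if c.kind is CommandKind.STIM_LED_OFF)
        assert off.time_s - on.time_s == pytest.approx(30.0)

    def test_inconsistent_log_rejected(self):
        import dataclasses

        log = self.make_log([("O",)])
        bad = dataclasses.replace(log.trials[0], t_stim_off=log.trials[0].t_stim_off - 1.0)
        log.trials[0] = bad
        with pytest.raises(ValueError, match="omission LED-off"):
            drive_apparatus(log)
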