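"""Closed-loop session controller for the 5-CSRTT training curriculum.

The controller consumes region detection events (from the variance
detector or the agent simulator) and drives the apparatus — gate, five
stimulus LEDs, magazine LED, and the food feeder — through a per-phase
finite-state machine.  Four phases make up the curriculum:

HABITUATION      lights on, food on magazine entry at most once per
                 ``habituation_food_interval_s``.
MAGAZINE         gate closed; cycles of magazine-light illumination (up to
                 ``magazine_light_max_s``) separated by dark gaps; an entry
                 during illumination is rewarded.
STIMULUS_LIGHT   gate up, all five stimulus lights on continuously; any
                 aperture entry switches them off and lights the magazine;
                 magazine re-entry closes the gate and delivers food.
FIVE_CSRTT       the full trial loop: hold/ITI, gate up, pre-stimulus
                 interval (PSI), one stimulus light for
                 ``stimulus_duration_s``, and classification of the first
                 aperture entry as CORRECT / INCORRECT / ANTICIPATORY /
                 OMISSION.

An "entry" is always the ONSET edge of a detection event; a fish already
inside a region when a window opens does not count until it leaves and
re-enters (matching the detector's Schmitt re-trigger rule).  All times
are quantized to the frame clock (1/fps s).
"""

from __future__ import annotations

import bisect
import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detect import DEFAULT_FPS, DetectionEvent

__all__ = [
    "Phase",
    "Outcome",
    "CommandKind",
    "SessionSchedule",
    "ApparatusCommand",
    "TrialRecord",
    "EventLog",
    "APERTURES",
    "MAGAZINE",
    "aperture_name",
    "quantize",
    "select_stimulus",
    "run_habituation",
    "run_magazine_training",
    "run_stimulus_light_training",
    "run_5csrtt_session",
    "run_session",
    "drive_apparatus",
]

MAGAZINE = "magazine"
APERTURES = tuple(f"aperture_{i}" for i in range(1, 6))


def aperture_name(position: int) -> str:
    if not 1 <= position <= 5:
        raise ValueError(f"aperture position must be 1..5, got {position}")
    return f"aperture_{position}"


def quantize(t: float, fps: float = DEFAULT_FPS) -> float:
    """Snap a time in seconds onto the frame clock (nearest frame)."""
    return round(t * fps) / fps


class Phase(enum.Enum):
    HABITUATION = "HABITUATION"
    MAGAZINE = "MAGAZINE"
    STIMULUS_LIGHT = "STIMULUS_LIGHT"
    FIVE_CSRTT = "FIVE_CSRTT"


class Outcome(enum.Enum):
    CORRECT = "CORRECT"
    INCORRECT = "INCORRECT"
    ANTICIPATORY = "ANTICIPATORY"
    OMISSION = "OMISSION"


class CommandKind(enum.Enum):
    GATE_UP = "GATE_UP"
    GATE_DOWN = "GATE_DOWN"
    STIM_LED_ON = "STIM_LED_ON"
    STIM_LED_OFF = "STIM_LED_OFF"
    MAG_LED_ON = "MAG_LED_ON"
    MAG_LED_OFF = "MAG_LED_OFF"
    FEED = "FEED"


@dataclass(frozen=True)
class SessionSchedule:
    """Protocol parameters for one session.

    Durations are in seconds.  ``psi_s`` is the pre-stimulus interval (5 s
    in the first 5-CSRTT phase, 10 s in the second); responses during the
    PSI are anticipatory.  ``gate_latency_s`` is the time the gate takes to
    raise: the apertures become accessible that long after the GATE_UP
    command.  ``rng_seed`` fixes the stimulus-position sequence.
    """

    phase: Phase = Phase.FIVE_CSRTT
    session_length_s: float = 1800.0
    psi_s: float = 5.0
    stimulus_duration_s: float = 30.0
    timeout_s: float = 20.0
    iti_s: float = 20.0
    initial_hold_s: float = 60.0
    magazine_light_max_s: float = 10.0
    magazine_gap_s: float = 30.0
    habituation_food_interval_s: float = 30.0
    feeder_steps_per_delivery: int = 20
    gate_latency_s: float = 0.5
    fps: float = DEFAULT_FPS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "session_length_s", "psi_s", "stimulus_duration_s", "timeout_s",
            "iti_s", "initial_hold_s", "magazine_light_max_s",
            "magazine_gap_s", "habituation_food_interval_s", "fps",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.gate_latency_s < 0:
            raise ValueError("gate_latency_s must be >= 0")
        if self.feeder_steps_per_delivery < 1:
            raise ValueError("feeder_steps_per_delivery must be >= 1")

    def q(self, t: float) -> float:
        return quantize(t, self.fps)


@dataclass(frozen=True)
class ApparatusCommand:
    """One actuator action: LED state change, gate motion or feeder steps.

    ``arg`` carries the stimulus index (1..5) for stimulus-LED commands and
    the step count for FEED; it is ``None`` otherwise.
    """

    time_s: float
    kind: CommandKind
    arg: int | None = None

    def __post_init__(self) -> None:
        if self.kind in (CommandKind.STIM_LED_ON, CommandKind.STIM_LED_OFF):
            if self.arg is None or not 1 <= self.arg <= 5:
                raise ValueError(f"stimulus index must be 1..5, got {self.arg}")
        elif self.kind is CommandKind.FEED:
            if self.arg is None or self.arg < 1:
                raise ValueError("FEED requires a positive step count")


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one 5-CSRTT trial.

    Latency is measured from stimulus onset and only defined for CORRECT
    and INCORRECT trials.  ``t_food`` is ``None`` when no food was
    delivered (all outcomes but CORRECT, or a correct trial where the fish
    never returned to the magazine).
    """

    trial_index: int
    stimulus_position: int | None
    outcome: Outcome
    response_latency_s: float | None
    responded_position: int | None
    t_trial_start: float
    t_psi_start: float | None
    t_stim_on: float | None
    t_stim_off: float | None
    t_response: float | None
    t_food: float | None

    def __post_init__(self) -> None:
        if self.outcome in (Outcome.CORRECT, Outcome.INCORRECT):
            if self.responded_position is None or self.response_latency_s is None:
                raise ValueError(f"{self.outcome.value} trial requires response fields")
            if self.response_latency_s < 0:
                raise ValueError("latency must be >= 0")
        else:
            if self.response_latency_s is not None:
                raise ValueError(f"{self.outcome.value} trial must not carry a latency")


@dataclass
class EventLog:
    """Complete record of one session: metadata, trials, commands, raw events."""

    fish_id: str
    session_id: int
    schedule: SessionSchedule
    trials: list[TrialRecord] = field(default_factory=list)
    commands: list[ApparatusCommand] = field(default_factory=list)
    detections: list[DetectionEvent] = field(default_factory=list)
    n_reinforcers: int = 0

    @property
    def phase(self) -> Phase:
        return self.schedule.phase

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def outcome_counts(self) -> dict[Outcome, int]:
        counts = {o: 0 for o in Outcome}
        for t in self.trials:
            counts[t.outcome] += 1
        return counts


# ---------------------------------------------------------------------------
# event stream helpers
# ---------------------------------------------------------------------------


class _OnsetIndex:
    """Sorted onset times per region, with windowed first-onset queries."""

    def __init__(self, events: Sequence[DetectionEvent]):
        last_t = -np.inf
        for ev in events:
            if ev.onset_time < last_t:
                raise ValueError(
                    f"malformed log: detection events out of time order at "
                    f"{ev.region!r} t={ev.onset_time}"
                )
            last_t = ev.onset_time
        ap: list[tuple[float, int]] = []
        mag: list[float] = []
        for ev in events:
            if ev.region == MAGAZINE:
                mag.append(ev.onset_time)
            elif ev.region in APERTURES:
                ap.append((ev.onset_time, int(ev.region.rsplit("_", 1)[1])))
            # other regions are ignored by the controller
        ap.sort()
        self._aperture = ap
        self._aperture_t = [t for t, _ in ap]
        self._magazine = sorted(mag)

    def first_aperture_onset(
        self, t_lo: float, t_hi: float
    ) -> tuple[float, int] | None:
        """First aperture onset with t_lo <= t < t_hi, any aperture."""
        i = bisect.bisect_left(self._aperture_t, t_lo)
        if i < len(self._aperture) and self._aperture[i][0] < t_hi:
            return self._aperture[i]
        return None

    def first_magazine_onset_after(self, t: float) -> float | None:
        """First magazine onset strictly after ``t``."""
        i = bisect.bisect_right(self._magazine, t)
        return self._magazine[i] if i < len(self._magazine) else None

    def magazine_onsets(self) -> list[float]:
        return list(self._magazine)


def select_stimulus(rng: np.random.Generator) -> int:
    """Draw the lit aperture uniformly from {1..5} (repeats allowed)."""
    return int(rng.integers(1, 6))


# ---------------------------------------------------------------------------
# phase controllers
# ---------------------------------------------------------------------------


def run_habituation(
    schedule: SessionSchedule,
    events: Sequence[DetectionEvent],
    fish_id: str = "fish",
    session_id: int = 0,
) -> EventLog:
    """Free food on magazine entry, rate-limited to one delivery per
    ``habituation_food_interval_s``.  No trials are scored."""
    if schedule.phase is not Phase.HABITUATION:
        raise ValueError("schedule phase must be HABITUATION")
    idx = _OnsetIndex(events)
    log = EventLog(fish_id, session_id, schedule, detections=list(events))
    last_delivery: float | None = None
    for t in idx.magazine_onsets():
        if t >= schedule.session_length_s:
            break
        if last_delivery is None or t - last_delivery >= schedule.habituation_food_interval_s:
            log.commands.append(
                ApparatusCommand(t, CommandKind.FEED, schedule.feeder_steps_per_delivery)
            )
            log.n_reinforcers += 1
            last_delivery = t
    return log


def run_magazine_training(
    schedule: SessionSchedule,
    events: Sequence[DetectionEvent],
    fish_id: str = "fish",
    session_id: int = 0,
) -> EventLog:
    """Magazine-light cycles behind the closed gate.

    The session opens with one dark gap (a settling period), then repeats:
    magazine LED on for up to ``magazine_light_max_s``; an entry during the
    illumination is rewarded and ends it; a ``magazine_gap_s`` dark gap
    follows either way.  Entries during a gap have no effect.
    """
    if schedule.phase is not Phase.MAGAZINE:
        raise ValueError("schedule phase must be MAGAZINE")
    idx = _OnsetIndex(events)
    log = EventLog(fish_id, session_id, schedule, detections=list(events))
    L = schedule.session_length_s
    t_c = schedule.q(schedule.magazine_gap_s)
    while t_c < L:
        log.commands.append(ApparatusCommand(t_c, CommandKind.MAG_LED_ON))
        t_end = schedule.q(t_c + schedule.magazine_light_max_s)
        entry = idx.first_magazine_onset_after(t_c - 1e-12)
        if entry is not None and entry < min(t_end, L):
            log.commands.append(ApparatusCommand(entry, CommandKind.MAG_LED_OFF))
            log.commands.append(
                ApparatusCommand(entry, CommandKind.FEED, schedule.feeder_steps_per_delivery)
            )
            log.n_reinforcers += 1
            t_c = schedule.q(entry + schedule.magazine_gap_s)
        else:
            log.commands.append(ApparatusCommand(t_end, CommandKind.MAG_LED_OFF))
            t_c = schedule.q(t_end + schedule.magazine_gap_s)
    return log


def run_stimulus_light_training(
    schedule: SessionSchedule,
    events: Sequence[DetectionEvent],
    fish_id: str = "fish",
    session_id: int = 0,
) -> EventLog:
    """All five stimulus lights on; any aperture entry arms the magazine.

    Cycle: gate up, all stimulus LEDs lit; first aperture entry switches
    them off and lights the magazine; the following magazine entry lowers
    the gate and delivers food; after ``iti_s`` the next cycle begins.  The
    first cycle starts after the ``initial_hold_s`` hold.
    """
    if schedule.phase is not Phase.STIMULUS_LIGHT:
        raise ValueError("schedule phase must be STIMULUS_LIGHT")
    idx = _OnsetIndex(events)
    log = EventLog(fish_id, session_id, schedule, detections=list(events))
    L = schedule.session_length_s
    t0 = schedule.q(schedule.initial_hold_s)
    while t0 < L:
        log.commands.append(ApparatusCommand(t0, CommandKind.GATE_UP))
        for i in range(1, 6):
            log.commands.append(ApparatusCommand(t0, CommandKind.STIM_LED_ON, i))
        t_open = schedule.q(t0 + schedule.gate_latency_s)
        hit = idx.first_aperture_onset(t_open, L)
        if hit is None:
            break
        t_a, _pos = hit
        for i in range(1, 6):
            log.commands.append(ApparatusCommand(t_a, CommandKind.STIM_LED_OFF, i))
        log.commands.append(ApparatusCommand(t_a, CommandKind.MAG_LED_ON))
        t_m = idx.first_magazine_onset_after(t_a)
        if t_m is None or t_m >= L:
            break
        log.commands.append(ApparatusCommand(t_m, CommandKind.GATE_DOWN))
        log.commands.append(ApparatusCommand(t_m, CommandKind.MAG_LED_OFF))
        log.commands.append(
            ApparatusCommand(t_m, CommandKind.FEED, schedule.feeder_steps_per_delivery)
        )
        log.n_reinforcers += 1
        t0 = schedule.q(t_m + schedule.iti_s)
    return log


def run_5csrtt_session(
    schedule: SessionSchedule,
    events: Sequence[DetectionEvent],
    fish_id: str = "fish",
    session_id: int = 0,
    max_trials: int | None = None,
) -> EventLog:
    """Run the full five-choice trial loop over a detection-event stream.

    Per trial: gate up, PSI wait, one stimulus light for
    ``stimulus_duration_s``, then the first aperture entry decides the
    outcome.  An entry during the PSI is ANTICIPATORY regardless of which
    aperture.  During the stimulus window, entry to the lit aperture is
    CORRECT (magazine light on, gate closes as the fish passes through,
    food on magazine entry, then ITI), any other aperture is INCORRECT; no
    entry is an OMISSION.  Non-correct outcomes are punished with lights
    off and a ``timeout_s`` confinement without food.  A trial whose
    outcome is not decided by session end is discarded.
    """
    if schedule.phase is not Phase.FIVE_CSRTT:
        raise ValueError("schedule phase must be FIVE_CSRTT")
    idx = _OnsetIndex(events)
    log = EventLog(fish_id, session_id, schedule, detections=list(events))
    rng = np.random.default_rng(schedule.rng_seed)
    L = schedule.session_length_s
    cmd = log.commands.append
    steps = schedule.feeder_steps_per_delivery

    t0 = schedule.q(schedule.initial_hold_s)
    trial_index = 0
    while t0 < L and (max_trials is None or trial_index < max_trials):
        stim_pos = select_stimulus(rng)
        t_open = schedule.q(t0 + schedule.gate_latency_s)
        t_stim = schedule.q(t_open + schedule.psi_s)
        t_win_end = schedule.q(t_stim + schedule.stimulus_duration_s)

        hit = idx.first_aperture_onset(t_open, t_win_end)
        record: TrialRecord | None = None
        commands: list[ApparatusCommand] = [ApparatusCommand(t0, CommandKind.GATE_UP)]

        if hit is not None and hit[0] < t_stim:
            # entry during the PSI: anticipatory, whatever the aperture
            t_r, pos = hit
            if t_r >= L:
                break
            commands.append(ApparatusCommand(t_r, CommandKind.GATE_DOWN))
            record = TrialRecord(
                trial_index, stim_pos, Outcome.ANTICIPATORY, None, pos,
                t0, t_open, None, None, t_r, None,
            )
            t_next = schedule.q(t_r + schedule.timeout_s)
        elif hit is not None:
            t_r, pos = hit
            if t_r >= L:
                break
            commands.append(ApparatusCommand(t_stim, CommandKind.STIM_LED_ON, stim_pos))
            commands.append(ApparatusCommand(t_r, CommandKind.STIM_LED_OFF, stim_pos))
            latency = round((t_r - t_stim) * schedule.fps) / schedule.fps
            if pos == stim_pos:
                commands.append(ApparatusCommand(t_r, CommandKind.MAG_LED_ON))
                t_m = idx.first_magazine_onset_after(t_r)
                t_food = t_m if (t_m is not None and t_m < L) else None
                if t_food is not None:
                    commands.append(ApparatusCommand(t_food, CommandKind.GATE_DOWN))
                    commands.append(ApparatusCommand(t_food, CommandKind.MAG_LED_OFF))
                    commands.append(ApparatusCommand(t_food, CommandKind.FEED, steps))
                    log.n_reinforcers += 1
                    t_next = schedule.q(t_food + schedule.iti_s)
                else:
                    t_next = L
                record = TrialRecord(
                    trial_index, stim_pos, Outcome.CORRECT, latency, pos,
                    t0, t_open, t_stim, t_r, t_r, t_food,
                )
            else:
                commands.append(ApparatusCommand(t_r, CommandKind.GATE_DOWN))
                record = TrialRecord(
                    trial_index, stim_pos, Outcome.INCORRECT, latency, pos,
                    t0, t_open, t_stim, t_r, t_r, None,
                )
                t_next = schedule.q(t_r + schedule.timeout_s)
        else:
            # no entry within the stimulus window: omission
            if t_win_end >= L:
                break
            commands.append(ApparatusCommand(t_stim, CommandKind.STIM_LED_ON, stim_pos))
            commands.append(ApparatusCommand(t_win_end, CommandKind.STIM_LED_OFF, stim_pos))
            commands.append(ApparatusCommand(t_win_end, CommandKind.GATE_DOWN))
            record = TrialRecord(
                trial_index, stim_pos, Outcome.OMISSION, None, None,
                t0, t_open, t_stim, t_win_end, None, None,
            )
            t_next = schedule.q(t_win_end + schedule.timeout_s)

        for c in commands:
            cmd(c)
        log.trials.append(record)
        trial_index += 1
        t0 = t_next

    log.commands.sort(key=lambda c: c.time_s)
    return log


_RUNNERS = {
    Phase.HABITUATION: run_habituation,
    Phase.MAGAZINE: run_magazine_training,
    Phase.STIMULUS_LIGHT: run_stimulus_light_training,
    Phase.FIVE_CSRTT: run_5csrtt_session,
}


def run_session(
    schedule: SessionSchedule,
    events: Sequence[DetectionEvent],
    fish_id: str = "fish",
    session_id: int = 0,
) -> EventLog:
    """Dispatch to the controller for ``schedule.phase``."""
    return _RUNNERS[schedule.phase](schedule, events, fish_id, session_id)


def drive_apparatus(log: EventLog) -> list[ApparatusCommand]:
    """Rebuild the apparatus command list from a 5-CSRTT log's trial records.

    Deterministic and validated: exactly one FEED per food-delivered
    CORRECT trial, none otherwise; the stimulus LED of an omission trial
    goes off exactly ``stimulus_duration_s`` after it came on.  Raises on
    an internally inconsistent log.
    """
    if log.phase is not Phase.FIVE_CSRTT:
        raise ValueError("drive_apparatus expects a FIVE_CSRTT log")
    sched = log.schedule
    steps = sched.feeder_steps_per_delivery
    out: list[ApparatusCommand] = []
    for tr in log.trials:
        out.append(ApparatusCommand(tr.t_trial_start, CommandKind.GATE_UP))
        if tr.outcome is Outcome.ANTICIPATORY:
            if tr.t_stim_on is not None or tr.t_food is not None:
                raise ValueError(f"trial {tr.trial_index}: inconsistent anticipatory record")
            out.append(ApparatusCommand(tr.t_response, CommandKind.GATE_DOWN))
            continue
        if tr.t_stim_on is None or tr.stimulus_position is None:
            raise ValueError(f"trial {tr.trial_index}: missing stimulus fields")
        out.append(ApparatusCommand(tr.t_stim_on, CommandKind.STIM_LED_ON, tr.stimulus_position))
        out.append(ApparatusCommand(tr.t_stim_off, CommandKind.STIM_LED_OFF, tr.stimulus_position))
        if tr.outcome is Outcome.OMISSION:
            if tr.t_food is not None:
                raise ValueError(f"trial {tr.trial_index}: food on an omission trial")
            off = round((tr.t_stim_off - tr.t_stim_on) * sched.fps) / sched.fps
            if off != sched.q(sched.stimulus_duration_s):
                raise ValueError(
                    f"trial {tr.trial_index}: omission LED-off not at stimulus end"
                )
            out.append(ApparatusCommand(tr.t_stim_off, CommandKind.GATE_DOWN))
        elif tr.outcome is Outcome.INCORRECT:
            if tr.t_food is not None:
                raise ValueError(f"trial {tr.trial_index}: food on an incorrect trial")
            out.append(ApparatusCommand(tr.t_response, CommandKind.GATE_DOWN))
        else:  # CORRECT
            out.append(ApparatusCommand(tr.t_response, CommandKind.MAG_LED_ON))
            if tr.t_food is not None:
                out.append(ApparatusCommand(tr.t_food, CommandKind.GATE_DOWN))
                out.append(ApparatusCommand(tr.t_food, CommandKind.MAG_LED_OFF))
                out.append(ApparatusCommand(tr.t_food, CommandKind.FEED, steps))
    out.sort(key=lambda c: c.time_s)
    n_feed = sum(1 for c in out if c.kind is CommandKind.FEED)
    n_fed_correct = sum(
        1 for tr in log.trials if tr.outcome is Outcome.CORRECT and tr.t_food is not None
    )
    if n_feed != n_fed_correct:
        raise ValueError("FEED count does not match fed correct trials")
    return out
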