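"""Stochastic fish agent: simulated behavior for closed-loop testing.

The agent generates the detection-event streams a real fish would produce
in the rig, with interpretable behavioral parameters:

* ``premature_hazard`` -- a homogeneous Poisson hazard (per second) of
  entering an aperture during the pre-stimulus interval, so a premature
  entry occurs on a trial with probability ``1 - exp(-hazard * psi)``.
  This is the simplest model that makes anticipatory responding increase
  with PSI length.
* ``p_respond`` -- probability of responding at all within the stimulus
  window (its complement is the omission propensity).
* ``p_correct`` -- probability a stimulus-window response targets the lit
  aperture; errors are uniform over the other four.
* log-normal response and magazine-return latencies (positive,
  right-skewed).

The simulator also records, trial by trial, the outcome it expects the
session controller to assign.  Feeding the simulated event stream through
:func:`fishrig.session.run_5csrtt_session` must reproduce those outcomes
exactly; that closed-loop identity is the main correctness oracle for the
controller.  ``recover_hazard`` inverts the premature-entry model by
maximum likelihood from logged sessions at one or more PSIs.
"""

from __future__ import annotations

import bisect
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .detect import DetectionEvent, Trajectory
from .session import (
    APERTURES,
    MAGAZINE,
    EventLog,
    Outcome,
    Phase,
    SessionSchedule,
    TrialRecord,
    aperture_name,
    select_stimulus,
)

__all__ = [
    "AgentParams",
    "SimulatedCohort",
    "TankGeometry",
    "default_geometry",
    "simulate_trial",
    "simulate_session",
    "recover_hazard",
    "recover_hazard_from_counts",
    "events_to_trajectory",
]


@dataclass(frozen=True)
class AgentParams:
    """Behavioral parameters of one simulated fish.

    Defaults describe a trained adult zebrafish that mostly responds
    (omissions are rare), chooses the lit aperture well above the 20%
    chance level, and shows a moderate impulsivity hazard.
    ``speed_accuracy_beta`` > 0 couples choice accuracy to the sampled
    latency through a logistic link (slower responses more accurate),
    emulating a speed-accuracy trade-off; it is off by default.
    """

    premature_hazard: float = 0.05     # lambda, premature entries / s of PSI
    p_correct: float = 0.6             # P(lit aperture | response)
    p_respond: float = 0.95            # P(any response within the window)
    latency_median_s: float = 5.0      # log-normal response latency median
    latency_sigma: float = 0.5         # log-normal shape (sd of log latency)
    magazine_return_median_s: float = 3.0
    magazine_return_sigma: float = 0.5
    dwell_s: float = 0.5               # occupancy duration of one entry
    speed_accuracy_beta: float = 0.0   # logistic slope of p_correct vs latency
    magazine_entry_rate: float = 0.05  # spontaneous magazine entries / s
    aperture_entry_rate: float = 0.02  # spontaneous aperture entries / s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.premature_hazard < 0:
            raise ValueError("premature_hazard must be >= 0")
        for name in ("p_correct", "p_respond"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("latency_median_s", "magazine_return_median_s", "dwell_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def _p_correct_at(self, latency: float) -> float:
        """Choice accuracy, optionally coupled to latency (logistic link)."""
        if self.speed_accuracy_beta == 0.0:
            return self.p_correct
        p0 = min(max(self.p_correct, 1e-9), 1 - 1e-9)
        alpha = math.log(p0 / (1 - p0)) - self.speed_accuracy_beta * self.latency_median_s
        return 1.0 / (1.0 + math.exp(-(alpha + self.speed_accuracy_beta * latency)))


@dataclass(frozen=True)
class SimulatedCohort:
    """A set of simulated fish with per-fish behavioral parameters."""

    fish: tuple[tuple[str, AgentParams], ...]

    def __post_init__(self) -> None:
        ids = [fid for fid, _ in self.fish]
        if len(set(ids)) != len(ids):
            raise ValueError("fish ids must be unique")

    @classmethod
    def draw(
        cls,
        n_fish: int,
        seed: int = 0,
        hazard_gamma_shape: float = 2.0,
        hazard_gamma_scale: float = 0.025,
        base: AgentParams = AgentParams(),
    ) -> "SimulatedCohort":
        """Draw per-fish parameters from population distributions.

        The premature hazard is gamma-distributed (mean ``shape * scale``,
        default 0.05/s), which yields the right-skewed between-fish
        distribution of anticipatory responding typical of mutagenized
        cohorts: most fish with low rates, a tail of high responders.
        """
        rng = np.random.default_rng(seed)
        fish = []
        for i in range(n_fish):
            lam = float(rng.gamma(hazard_gamma_shape, hazard_gamma_scale))
            agent_seed = int(rng.integers(0, 2**31 - 1))
            fish.append(
                (f"fish_{i:03d}", replace(base, premature_hazard=lam, seed=agent_seed))
            )
        return cls(tuple(fish))


# ---------------------------------------------------------------------------
# trial and session simulation
# ---------------------------------------------------------------------------


def _entry(region: str, t: float, dwell: float, sched: SessionSchedule) -> DetectionEvent:
    fps = sched.fps
    f_on = round(t * fps)
    f_off = max(f_on + 1, round((t + dwell) * fps))
    return DetectionEvent(region, f_on, f_off, f_on / fps, f_off / fps)


def _trunc_lognormal(
    rng: np.random.Generator, median: float, sigma: float, upper: float
) -> float:
    """Log-normal sample conditioned on being below ``upper``."""
    mu = math.log(median)
    for _ in range(1000):
        x = float(rng.lognormal(mu, sigma))
        if x < upper:
            return x
    # pathological parameters: fall back to the upper bound interior
    return 0.5 * upper


def simulate_trial(
    agent: AgentParams,
    schedule: SessionSchedule,
    rng: np.random.Generator,
    t0: float = 60.0,
    trial_index: int = 0,
    stimulus_position: int | None = None,
) -> tuple[list[DetectionEvent], TrialRecord, float]:
    """Simulate one 5-CSRTT trial starting with GATE_UP at ``t0``.

    Returns the emitted detection events, the trial record the controller
    is expected to produce, and the start time of the next trial.  The
    stimulus position is drawn from ``rng`` when not supplied (the real
    fish sees the light; the simulated one is told which aperture is lit).

    All event times are quantized to the frame clock before the expected
    outcome is derived, so the expectation applies exactly the same
    classification windows as the controller.
    """
    if schedule.phase is not Phase.FIVE_CSRTT:
        raise ValueError("simulate_trial expects a FIVE_CSRTT schedule")
    q = schedule.q
    frame = 1.0 / schedule.fps
    stim_pos = select_stimulus(rng) if stimulus_position is None else stimulus_position
    t_open = q(t0 + schedule.gate_latency_s)
    t_stim = q(t_open + schedule.psi_s)
    t_win_end = q(t_stim + schedule.stimulus_duration_s)
    events: list[DetectionEvent] = []

    # premature aperture entry: exponential waiting time from gate-open
    d = rng.exponential(1.0 / agent.premature_hazard) if agent.premature_hazard > 0 else math.inf
    if d < schedule.psi_s:
        pos = int(rng.integers(1, 6))
        t_r = q(t_open + d)
        events.append(_entry(aperture_name(pos), t_r, agent.dwell_s, schedule))
        if t_r < t_stim:
            record = TrialRecord(
                trial_index, stim_pos, Outcome.ANTICIPATORY, None, pos,
                t0, t_open, None, None, t_r, None,
            )
            return events, record, q(t_r + schedule.timeout_s)
        # quantization pushed the entry onto the stimulus-onset frame:
        # it is a stimulus-window response at zero latency
        return _finish_response(
            agent, schedule, rng, events, trial_index, stim_pos, pos,
            t0, t_open, t_stim, t_r,
        )

    if rng.random() >= agent.p_respond:
        record = TrialRecord(
            trial_index, stim_pos, Outcome.OMISSION, None, None,
            t0, t_open, t_stim, t_win_end, None, None,
        )
        return events, record, q(t_win_end + schedule.timeout_s)

    lat = _trunc_lognormal(
        rng, agent.latency_median_s, agent.latency_sigma, schedule.stimulus_duration_s
    )
    t_r = q(t_stim + lat)
    if t_r >= t_win_end:          # rounding up at the window edge
        t_r = q(t_win_end - frame)
    if rng.random() < agent._p_correct_at(lat):
        pos = stim_pos
    else:
        others = [p for p in range(1, 6) if p != stim_pos]
        pos = others[int(rng.integers(0, 4))]
    events.append(_entry(aperture_name(pos), t_r, agent.dwell_s, schedule))
    return _finish_response(
        agent, schedule, rng, events, trial_index, stim_pos, pos,
        t0, t_open, t_stim, t_r,
    )


def _finish_response(
    agent: AgentParams,
    schedule: SessionSchedule,
    rng: np.random.Generator,
    events: list[DetectionEvent],
    trial_index: int,
    stim_pos: int,
    pos: int,
    t0: float,
    t_open: float,
    t_stim: float,
    t_r: float,
) -> tuple[list[DetectionEvent], TrialRecord, float]:
    q = schedule.q
    frame = 1.0 / schedule.fps
    latency = round((t_r - t_stim) * schedule.fps) / schedule.fps
    if pos == stim_pos:
        back = float(
            rng.lognormal(math.log(agent.magazine_return_median_s), agent.magazine_return_sigma)
        )
        t_m = q(t_r + max(back, frame))
        if t_m <= t_r:
            t_m = q(t_r + frame)
        events.append(_entry(MAGAZINE, t_m, agent.dwell_s, schedule))
        if t_m < schedule.session_length_s:
            t_food = t_m
            t_next = q(t_m + schedule.iti_s)
        else:
            t_food = None
            t_next = schedule.session_length_s
        record = TrialRecord(
            trial_index, stim_pos, Outcome.CORRECT, latency, pos,
            t0, t_open, t_stim, t_r, t_r, t_food,
        )
        return events, record, t_next
    record = TrialRecord(
        trial_index, stim_pos, Outcome.INCORRECT, latency, pos,
        t0, t_open, t_stim, t_r, t_r, None,
    )
    return events, record, q(t_r + schedule.timeout_s)


def _simulate_5csrtt(
    agent: AgentParams,
    schedule: SessionSchedule,
    fish_id: str,
    session_id: int,
    max_trials: int | None,
) -> EventLog:
    behavior = np.random.default_rng(agent.seed)
    stim_rng = np.random.default_rng(schedule.rng_seed)
    L = schedule.session_length_s
    log = EventLog(fish_id, session_id, schedule)
    t0 = schedule.q(schedule.initial_hold_s)
    trial_index = 0
    while t0 < L and (max_trials is None or trial_index < max_trials):
        stim_pos = select_stimulus(stim_rng)
        events, record, t_next = simulate_trial(
            agent, schedule, behavior, t0, trial_index, stim_pos
        )
        # outcome decided at or after session end: trial discarded
        decided = record.t_response if record.t_response is not None else record.t_stim_off
        if decided >= L:
            log.detections.extend(events)
            break
        log.detections.extend(events)
        log.trials.append(record)
        if record.t_food is not None:
            log.n_reinforcers += 1
        trial_index += 1
        t0 = t_next
    return log


def _poisson_onsets(
    rng: np.random.Generator, rate: float, t_start: float, t_end: float
) -> list[float]:
    times = []
    t = t_start
    if rate <= 0:
        return times
    while True:
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            return times
        times.append(t)


def _simulate_magazine_visits(
    agent: AgentParams, schedule: SessionSchedule, fish_id: str, session_id: int
) -> EventLog:
    """Habituation/magazine phases: spontaneous magazine entries only."""
    rng = np.random.default_rng(agent.seed)
    raw = _poisson_onsets(rng, agent.magazine_entry_rate, 0.0, schedule.session_length_s)
    events = []
    last_off = -math.inf
    for t in raw:
        tq = schedule.q(t)
        if tq <= last_off:        # keep per-region events disjoint
            continue
        ev = _entry(MAGAZINE, tq, agent.dwell_s, schedule)
        events.append(ev)
        last_off = ev.offset_time
    from .session import run_session  # local import to avoid cycle at module load
    return run_session(schedule, events, fish_id, session_id)


def _simulate_stimulus_light(
    agent: AgentParams, schedule: SessionSchedule, fish_id: str, session_id: int
) -> EventLog:
    """Stimulus-light phase: aperture visit, then magazine return, repeat."""
    rng = np.random.default_rng(agent.seed)
    L = schedule.session_length_s
    events: list[DetectionEvent] = []
    t = schedule.q(schedule.initial_hold_s + schedule.gate_latency_s)
    while True:
        if agent.aperture_entry_rate <= 0:
            break
        t_a = schedule.q(t + rng.exponential(1.0 / agent.aperture_entry_rate))
        if t_a >= L:
            break
        pos = int(rng.integers(1, 6))
        events.append(_entry(aperture_name(pos), t_a, agent.dwell_s, schedule))
        back = float(
            rng.lognormal(math.log(agent.magazine_return_median_s), agent.magazine_return_sigma)
        )
        t_m = schedule.q(t_a + max(back, 1.0 / schedule.fps))
        if t_m >= L:
            break
        events.append(_entry(MAGAZINE, t_m, agent.dwell_s, schedule))
        t = schedule.q(t_m + schedule.iti_s + schedule.gate_latency_s)
    from .session import run_session
    return run_session(schedule, events, fish_id, session_id)


def simulate_session(
    agent: AgentParams,
    schedule: SessionSchedule,
    fish_id: str = "fish",
    session_id: int = 0,
    max_trials: int | None = None,
) -> EventLog:
    """Simulate one full session of the schedule's phase.

    For FIVE_CSRTT the returned log carries the simulator's own expected
    trial records alongside the raw event stream; running the controller
    on ``log.detections`` must reproduce ``log.trials`` exactly.  For the
    pre-training phases the event stream is generated from simple visit
    processes and scored by the corresponding phase controller.
    """
    if schedule.phase is Phase.FIVE_CSRTT:
        return _simulate_5csrtt(agent, schedule, fish_id, session_id, max_trials)
    if schedule.phase in (Phase.HABITUATION, Phase.MAGAZINE):
        return _simulate_magazine_visits(agent, schedule, fish_id, session_id)
    return _simulate_stimulus_light(agent, schedule, fish_id, session_id)


# ---------------------------------------------------------------------------
# hazard-rate recovery
# ---------------------------------------------------------------------------


def recover_hazard_from_counts(counts: dict[float, tuple[int, int]]) -> float:
    """Maximum-likelihood premature hazard from anticipatory counts.

    ``counts`` maps PSI (seconds) to ``(n_anticipatory, n_trials)``.
    Under the exponential-hazard model a trial at PSI ``t`` is anticipatory
    with probability ``1 - exp(-lambda t)``; the binomial log-likelihood is
    maximized over ``lambda >= 0``.  Returns 0.0 (with a warning) when no
    anticipatory responses were observed at any PSI.
    """
    items = [(t, k, m) for t, (k, m) in counts.items() if m > 0]
    if not items:
        raise ValueError("no trials in counts")
    if all(k == 0 for _t, k, _m in items):
        warnings.warn(
            "no anticipatory responses at any PSI: hazard estimate is at the "
            "boundary (0)", RuntimeWarning,
        )
        return 0.0
    if all(k == m for _t, k, m in items):
        warnings.warn(
            "every trial anticipatory at every PSI: hazard unbounded",
            RuntimeWarning,
        )
        return math.inf

    def neg_ll(lam: float) -> float:
        ll = 0.0
        for t, k, m in items:
            p = -math.expm1(-lam * t)       # 1 - exp(-lam t), stable near 0
            if k > 0:
                ll += k * math.log(p)
            ll += (m - k) * (-lam * t)
        return -ll

    res = optimize.minimize_scalar(
        neg_ll, bounds=(1e-10, 100.0), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def recover_hazard(logs: Sequence[EventLog]) -> float:
    """MLE premature hazard pooled over 5-CSRTT session logs (any PSIs)."""
    counts: dict[float, tuple[int, int]] = {}
    for log in logs:
        if log.phase is not Phase.FIVE_CSRTT:
            raise ValueError("recover_hazard expects FIVE_CSRTT logs")
        psi = log.schedule.psi_s
        k, m = counts.get(psi, (0, 0))
        k += sum(1 for tr in log.trials if tr.outcome is Outcome.ANTICIPATORY)
        m += len(log.trials)
        counts[psi] = (k, m)
    return recover_hazard_from_counts(counts)


# ---------------------------------------------------------------------------
# event stream -> trajectory (for end-to-end video tests)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TankGeometry:
    """Maps controller regions to pixel ROIs of the synthetic scene."""

    frame_shape: tuple[int, int]
    rois: dict[str, tuple[int, int, int, int]]
    home: tuple[float, float]   # resting position outside every ROI

    def center(self, region: str) -> tuple[float, float]:
        r0, c0, r1, c1 = self.rois[region]
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


def default_geometry(
    frame_shape: tuple[int, int] = (360, 640),
    fish_length_px: int = 30,
    fish_width_px: int = 5,
) -> TankGeometry:
    """Five aperture ROIs along the top edge, magazine at the bottom.

    ROI boxes are sized to fully contain the fish streak; frames narrower
    than about seven streak lengths cannot host five disjoint apertures
    and are rejected.
    """
    nrow, ncol = frame_shape
    box_w = max(fish_length_px + 4, ncol // 12)
    box_h = max(fish_width_px + 4, nrow // 10)
    gap = ncol // 5
    if gap < box_w + 2 or nrow < 3 * box_h + 20:
        raise ValueError(f"frame {frame_shape} too small for the tank geometry")
    rois: dict[str, tuple[int, int, int, int]] = {}
    for i in range(5):
        c0 = gap * i + (gap - box_w) // 2
        rois[aperture_name(i + 1)] = (10, c0, 10 + box_h, c0 + box_w)
    mc0 = (ncol - box_w) // 2
    rois[MAGAZINE] = (nrow - 10 - box_h, mc0, nrow - 10, mc0 + box_w)
    home = (nrow / 2.0, ncol / 2.0)
    return TankGeometry(frame_shape, rois, home)


def events_to_trajectory(
    log: EventLog | Sequence[DetectionEvent],
    geometry: TankGeometry,
    n_frames: int | None = None,
) -> Trajectory:
    """Piecewise trajectory that sits inside region R exactly during R's events.

    Outside every event the fish rests at ``geometry.home``.  Overlapping
    events in different regions cannot be realized by a single fish and
    raise an infeasible-path error.
    """
    events = log.detections if isinstance(log, EventLog) else list(log)
    intervals: list[tuple[int, int, str]] = []
    for ev in events:
        if ev.region not in geometry.rois:
            raise KeyError(f"no ROI for region {ev.region!r} in geometry")
        end = ev.offset_frame if ev.offset_frame is not None else (
            n_frames if n_frames is not None else ev.onset_frame + 1
        )
        intervals.append((ev.onset_frame, end, ev.region))
    intervals.sort()
    for (a0, a1, ra), (b0, b1, rb) in zip(intervals, intervals[1:]):
        if b0 < a1 and ra != rb:
            raise ValueError(
                f"infeasible path: overlapping events in {ra!r} and {rb!r} "
                f"(frames {b0} < {a1})"
            )
    starts = [iv[0] for iv in intervals]

    def traj(index: int) -> tuple[float, float] | None:
        i = bisect.bisect_right(starts, index) - 1
        if i >= 0:
            a0, a1, region = intervals[i]
            if a0 <= index < a1:
                return geometry.center(region)
        return geometry.home

    return traj
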