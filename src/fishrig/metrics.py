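"""Session-level behavioral metrics, attrition screening and exports.

The standard 5-CSRTT performance parameters are computed from per-trial
outcome counts::

    accuracy     = correct / (correct + incorrect)
    anticipatory = early   / (correct + incorrect + early)
    omissions    = omitted / (correct + incorrect + early + omitted)

where "early" counts anticipatory responses.  A proportion whose
denominator is zero is *undefined* (NaN), never 0 -- reporting 0 would
silently bias cohort means.  Mean correct latency averages response
latencies over CORRECT trials only, measured from stimulus onset.

The attrition screen drops fish that died and fish whose mean number of
trials per session during training was not strictly greater than 10.
Learning during pre-training phases is summarized by the per-fish
ordinary-least-squares slope of reinforcers earned against session index.
Mixed-effects modeling of the resulting long-format tables is left to
external statistics packages; this module only prepares the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .session import EventLog, Outcome, Phase

__all__ = [
    "SessionMetrics",
    "FishSummary",
    "summarize_session",
    "summarize_counts",
    "attrition_screen",
    "learning_slope",
    "phase_contrast",
    "speed_accuracy_table",
    "metrics_frame",
]

TRIALS_CRITERION = 10.0  # mean trials/session must strictly exceed this


@dataclass(frozen=True)
class SessionMetrics:
    """Outcome counts and the derived proportions for one session."""

    n_correct: int
    n_incorrect: int
    n_anticipatory: int
    n_omission: int
    accuracy: float
    anticipatory_prop: float
    omission_prop: float
    mean_correct_latency_s: float
    n_trials: int

    def as_dict(self) -> dict:
        return {
            "n_correct": self.n_correct,
            "n_incorrect": self.n_incorrect,
            "n_anticipatory": self.n_anticipatory,
            "n_omission": self.n_omission,
            "accuracy": self.accuracy,
            "anticipatory_prop": self.anticipatory_prop,
            "omission_prop": self.omission_prop,
            "mean_correct_latency_s": self.mean_correct_latency_s,
            "n_trials": self.n_trials,
        }


@dataclass(frozen=True)
class FishSummary:
    """Per-fish training summary used by the attrition screen."""

    fish_id: str
    sessions: tuple[SessionMetrics, ...]
    mean_trials_per_session: float
    dead: bool = False
    learning_slope: float = float("nan")

    @property
    def retained(self) -> bool:
        return (not self.dead) and self.mean_trials_per_session > TRIALS_CRITERION


def summarize_counts(
    n_correct: int,
    n_incorrect: int,
    n_anticipatory: int,
    n_omission: int,
    mean_correct_latency_s: float = float("nan"),
) -> SessionMetrics:
    """Metrics from raw outcome counts (formulas above; NaN over zero)."""
    for v in (n_correct, n_incorrect, n_anticipatory, n_omission):
        if v < 0:
            raise ValueError("counts must be nonnegative")
    responded = n_correct + n_incorrect
    committed = responded + n_anticipatory
    total = committed + n_omission
    accuracy = n_correct / responded if responded > 0 else float("nan")
    anticipatory = n_anticipatory / committed if committed > 0 else float("nan")
    omission = n_omission / total if total > 0 else float("nan")
    return SessionMetrics(
        n_correct, n_incorrect, n_anticipatory, n_omission,
        accuracy, anticipatory, omission, mean_correct_latency_s, total,
    )


def summarize_session(log: EventLog) -> SessionMetrics:
    """Outcome counts, proportions and mean correct latency for one log."""
    counts = log.outcome_counts()
    lats = [
        t.response_latency_s for t in log.trials
        if t.outcome is Outcome.CORRECT and t.response_latency_s is not None
    ]
    mean_lat = float(np.mean(lats)) if lats else float("nan")
    return summarize_counts(
        counts[Outcome.CORRECT],
        counts[Outcome.INCORRECT],
        counts[Outcome.ANTICIPATORY],
        counts[Outcome.OMISSION],
        mean_lat,
    )


def attrition_screen(
    summaries: Sequence[FishSummary],
    deaths: Iterable[str] = (),
) -> tuple[list[FishSummary], list[FishSummary]]:
    """Partition a cohort into (retained, rejected).

    Rejected = fish that died plus fish whose mean trials/session is not
    strictly above the criterion (10).  ``deaths`` may name fish beyond
    those already flagged ``dead`` on their summary.
    """
    ids = [s.fish_id for s in summaries]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate fish ids: {dupes}")
    dead_ids = set(deaths)
    retained, rejected = [], []
    for s in summaries:
        is_dead = s.dead or s.fish_id in dead_ids
        if not is_dead and s.mean_trials_per_session > TRIALS_CRITERION:
            retained.append(s)
        else:
            rejected.append(s)
    return retained, rejected


def learning_slope(reinforcers_per_session: Sequence[float]) -> float:
    """OLS slope of reinforcers earned vs session index (1-based)."""
    y = np.asarray(reinforcers_per_session, dtype=np.float64)
    if y.size < 2:
        raise ValueError("learning_slope requires >= 2 sessions")
    x = np.arange(1, y.size + 1, dtype=np.float64)
    return float(np.polyfit(x, y, 1)[0])


def metrics_frame(logs: Sequence[EventLog]) -> pd.DataFrame:
    """Long-format per-session metrics table over many logs."""
    rows = []
    for log in logs:
        m = summarize_session(log)
        rows.append(
            {
                "fish_id": log.fish_id,
                "session": log.session_id,
                "phase": log.phase.value,
                "psi_s": log.schedule.psi_s,
                "n_reinforcers": log.n_reinforcers,
                **m.as_dict(),
            }
        )
    return pd.DataFrame(rows)


def phase_contrast(
    logs: Sequence[EventLog],
    metric: str = "anticipatory_prop",
    phase1_last_k: int = 4,
    phase2_first_k: int = 4,
) -> pd.DataFrame:
    """Per-fish paired means over the boundary between two 5-CSRTT phases.

    Phase 1 / phase 2 are the logs at the lower / higher PSI (typically
    5 s then 10 s).  For each fish the metric is averaged over the last
    ``phase1_last_k`` sessions of phase 1 and the first ``phase2_first_k``
    sessions of phase 2 (sessions ordered by session id).  Fish lacking
    enough sessions in either window are excluded with a warning.  The
    returned frame has one row per fish: ``fish_id, phase1_mean,
    phase2_mean, difference`` -- ready for external paired/mixed-model
    analysis.
    """
    csrtt = [log for log in logs if log.phase is Phase.FIVE_CSRTT]
    psis = sorted({log.schedule.psi_s for log in csrtt})
    if len(psis) != 2:
        raise ValueError(f"expected logs at exactly two PSIs, got {psis}")
    lo, hi = psis
    table = metrics_frame(csrtt)
    rows = []
    for fish_id, grp in table.groupby("fish_id", sort=True):
        g1 = grp[grp["psi_s"] == lo].sort_values("session")
        g2 = grp[grp["psi_s"] == hi].sort_values("session")
        if len(g1) < phase1_last_k or len(g2) < phase2_first_k:
            warnings.warn(
                f"fish {fish_id!r} excluded from phase contrast: "
                f"{len(g1)}/{len(g2)} sessions available, "
                f"{phase1_last_k}/{phase2_first_k} required",
                RuntimeWarning,
            )
            continue
        m1 = float(g1[metric].tail(phase1_last_k).mean())
        m2 = float(g2[metric].head(phase2_first_k).mean())
        rows.append(
            {"fish_id": fish_id, "phase1_mean": m1, "phase2_mean": m2,
             "difference": m2 - m1}
        )
    return pd.DataFrame(rows, columns=["fish_id", "phase1_mean", "phase2_mean", "difference"])


def speed_accuracy_table(logs: Sequence[EventLog]) -> pd.DataFrame:
    """One row per responded (CORRECT or INCORRECT) trial.

    Columns: fish_id, session, trial, latency_s, correct (bool).  Omission
    and anticipatory trials carry no response latency and are excluded.
    The table is the raw material for an external speed-accuracy analysis.
    """
    rows = []
    for log in logs:
        for tr in log.trials:
            if tr.outcome in (Outcome.CORRECT, Outcome.INCORRECT):
                rows.append(
                    {
                        "fish_id": log.fish_id,
                        "session": log.session_id,
                        "trial": tr.trial_index,
                        "latency_s": tr.response_latency_s,
                        "correct": tr.outcome is Outcome.CORRECT,
                    }
                )
    return pd.DataFrame(rows, columns=["fish_id", "session", "trial", "latency_s", "correct"])
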