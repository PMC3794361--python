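"""Run configuration and the end-to-end pipeline.

A run config describes a whole simulated experiment: a cohort of agents,
a sequence of training phases (each a block of sessions at one schedule),
and a global seed.  ``end_to_end`` executes simulate -> run sessions ->
analyze, writing per-session logs, metric tables and a manifest that ties
every output to its inputs and seeds.

Seeding: the global seed is fanned out with ``numpy.random.SeedSequence``
keyed by (seed, fish index, phase index, session index), so per-fish and
per-session streams are independent and adding a fish or a phase never
perturbs the streams of the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .agent import AgentParams, SimulatedCohort, simulate_session
from .io import (
    _load_structured,
    list_log_stems,
    read_event_log,
    schedule_from_dict,
    write_event_log,
)
from .metrics import (
    FishSummary,
    metrics_frame,
    phase_contrast,
    speed_accuracy_table,
    summarize_session,
)
from .session import EventLog, Phase, SessionSchedule

__all__ = ["PhaseBlock", "RunConfig", "validate_config", "end_to_end", "analyze_logs",
           "derive_seed", "build_summaries"]


def derive_seed(*key: int) -> int:
    """Stable 31-bit seed derived from an integer key path."""
    ss = np.random.SeedSequence(list(key))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass(frozen=True)
class PhaseBlock:
    """One block of identical sessions (a training phase)."""

    phase: Phase
    n_sessions: int
    schedule_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full simulated experiment."""

    seed: int = 0
    fps: float = 50.0
    n_fish: int = 2
    hazard_gamma_shape: float = 2.0
    hazard_gamma_scale: float = 0.025
    agent_overrides: dict = field(default_factory=dict)
    schedule_defaults: dict = field(default_factory=dict)
    phases: tuple[PhaseBlock, ...] = ()

    def schedule_for(self, block: PhaseBlock, rng_seed: int) -> SessionSchedule:
        data = {"fps": self.fps, **self.schedule_defaults,
                **block.schedule_overrides,
                "phase": block.phase, "rng_seed": rng_seed}
        return schedule_from_dict(data, source="run config schedule")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "fps": self.fps,
            "n_fish": self.n_fish,
            "hazard_gamma_shape": self.hazard_gamma_shape,
            "hazard_gamma_scale": self.hazard_gamma_scale,
            "agent_overrides": dict(self.agent_overrides),
            "schedule_defaults": dict(self.schedule_defaults),
            "phases": [
                {"phase": b.phase.value, "n_sessions": b.n_sessions,
                 "schedule_overrides": dict(b.schedule_overrides)}
                for b in self.phases
            ],
        }


def validate_config(data: dict | str | Path) -> RunConfig:
    """Validate a run config mapping (or config file path) into a RunConfig.

    Fills defaults (fps 50; schedule defaults psi 5 s, stimulus 30 s,
    timeout 20 s per ``SessionSchedule``) and raises a specific diagnostic
    for each missing field, out-of-range value or unknown key.
    """
    if isinstance(data, (str, Path)):
        loaded = _load_structured(data)
        if not isinstance(loaded, dict):
            raise ValueError(f"{data}: run config must be a mapping")
        data = loaded
    data = dict(data)
    known = {"seed", "fps", "n_fish", "hazard_gamma_shape", "hazard_gamma_scale",
             "agent_overrides", "schedule_defaults", "phases"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"run config: unknown fields {sorted(unknown)}")

    phases_raw = data.pop("phases", [])
    blocks = []
    for i, item in enumerate(phases_raw):
        if "phase" not in item:
            raise ValueError(f"run config: phases[{i}] missing 'phase'")
        try:
            phase = Phase(str(item["phase"]).upper())
        except ValueError as exc:
            raise ValueError(f"run config: phases[{i}]: unknown phase {item['phase']!r}") from exc
        blocks.append(
            PhaseBlock(phase, int(item.get("n_sessions", 1)),
                       dict(item.get("schedule_overrides", {})))
        )
    cfg = RunConfig(phases=tuple(blocks), **data)
    if cfg.n_fish < 1:
        raise ValueError("run config: n_fish must be >= 1")
    if cfg.fps <= 0:
        raise ValueError("run config: fps must be > 0")
    # validate agent overrides and every block's schedule eagerly so bad
    # ranges (e.g. psi_s <= 0) fail at config time, not mid-run
    AgentParams(**{**cfg.agent_overrides})
    for block in cfg.phases:
        cfg.schedule_for(block, rng_seed=0)
    return cfg


def default_demo_config(seed: int = 0) -> RunConfig:
    """Small demonstration experiment: 2 fish, 3 sessions at PSI 5 then 10."""
    return validate_config(
        {
            "seed": seed,
            "n_fish": 2,
            "schedule_defaults": {"session_length_s": 1800.0},
            "phases": [
                {"phase": "FIVE_CSRTT", "n_sessions": 3,
                 "schedule_overrides": {"psi_s": 5.0}},
                {"phase": "FIVE_CSRTT", "n_sessions": 3,
                 "schedule_overrides": {"psi_s": 10.0}},
            ],
        }
    )


def simulate_experiment(cfg: RunConfig) -> list[EventLog]:
    """Simulate every (fish, phase, session) of the configured experiment."""
    base = AgentParams(**cfg.agent_overrides)
    cohort = SimulatedCohort.draw(
        cfg.n_fish, seed=derive_seed(cfg.seed, 1000),
        hazard_gamma_shape=cfg.hazard_gamma_shape,
        hazard_gamma_scale=cfg.hazard_gamma_scale,
        base=base,
    )
    logs: list[EventLog] = []
    session_counter: dict[str, int] = {}
    for fi, (fish_id, params) in enumerate(cohort.fish):
        for pi, block in enumerate(cfg.phases):
            for si in range(block.n_sessions):
                sched = cfg.schedule_for(block, rng_seed=derive_seed(cfg.seed, fi, pi, si, 1))
                agent = dataclasses.replace(
                    params, seed=derive_seed(cfg.seed, fi, pi, si, 2)
                )
                sess_id = session_counter.get(fish_id, 0)
                session_counter[fish_id] = sess_id + 1
                logs.append(simulate_session(agent, sched, fish_id, sess_id))
    return logs


def build_summaries(logs: Sequence[EventLog]) -> list[FishSummary]:
    """Per-fish summaries over the 5-CSRTT logs (for the attrition screen)."""
    by_fish: dict[str, list[EventLog]] = {}
    for log in logs:
        if log.phase is Phase.FIVE_CSRTT:
            by_fish.setdefault(log.fish_id, []).append(log)
    out = []
    for fish_id in sorted(by_fish):
        flogs = sorted(by_fish[fish_id], key=lambda l: l.session_id)
        sess = tuple(summarize_session(l) for l in flogs)
        mean_trials = float(np.mean([m.n_trials for m in sess])) if sess else 0.0
        out.append(FishSummary(fish_id, sess, mean_trials))
    return out


def analyze_logs(logs: Sequence[EventLog], out_dir: str | Path) -> dict[str, Path]:
    """Write the standard analysis tables for a set of logs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    table = metrics_frame(logs)
    outputs["session_metrics"] = out_dir / "session_metrics.csv"
    table.to_csv(outputs["session_metrics"], index=False)

    sat = speed_accuracy_table([l for l in logs if l.phase is Phase.FIVE_CSRTT])
    outputs["speed_accuracy"] = out_dir / "speed_accuracy.csv"
    sat.to_csv(outputs["speed_accuracy"], index=False)

    csrtt = [l for l in logs if l.phase is Phase.FIVE_CSRTT]
    psis = sorted({l.schedule.psi_s for l in csrtt})
    if len(psis) == 2:
        # clamp the contrast windows to the sessions actually run
        counts: dict[tuple[str, float], int] = {}
        for l in csrtt:
            key = (l.fish_id, l.schedule.psi_s)
            counts[key] = counts.get(key, 0) + 1
        k1 = min(4, min(counts.get((f, psis[0]), 0) for f, _ in counts))
        k2 = min(4, min(counts.get((f, psis[1]), 0) for f, _ in counts))
        pc = phase_contrast(csrtt, phase1_last_k=max(k1, 1), phase2_first_k=max(k2, 1))
        outputs["phase_contrast"] = out_dir / "phase_contrast.csv"
        pc.to_csv(outputs["phase_contrast"], index=False)

    summaries = build_summaries(logs)
    if summaries:
        rows = [
            {"fish_id": s.fish_id, "n_sessions": len(s.sessions),
             "mean_trials_per_session": s.mean_trials_per_session,
             "retained": s.retained}
            for s in summaries
        ]
        import pandas as pd
        outputs["fish_summaries"] = out_dir / "fish_summaries.csv"
        pd.DataFrame(rows).to_csv(outputs["fish_summaries"], index=False)
    return outputs


def end_to_end(cfg: RunConfig, out_dir: str | Path) -> dict:
    """simulate cohort -> run sessions -> analyze; returns the manifest."""
    out_dir = Path(out_dir)
    logs_dir = out_dir / "logs"
    logs = simulate_experiment(cfg)
    for log in logs:
        write_event_log(log, logs_dir)
    tables = analyze_logs(logs, out_dir / "analysis")
    manifest = {
        "package": "fishrig",
        "version": __version__,
        "config": cfg.to_dict(),
        "n_logs": len(logs),
        "logs_dir": str(logs_dir),
        "outputs": {k: str(v) for k, v in sorted(tables.items())},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_logs(directory: str | Path) -> list[EventLog]:
    """Read every session log found in a directory."""
    return [read_event_log(directory, stem) for stem in list_log_stems(directory)]
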