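"""File formats: event CSVs, session logs, ROI / schedule / run configs.

Everything on disk is plain text: CSV for tabular data (events, trials,
commands), JSON for log metadata, YAML or JSON for configuration.  Event
logs round-trip exactly: ``read_event_log(write_event_log(log)) == log``.
Floats are serialized with ``repr``, which Python guarantees to round-trip
bit-exactly.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .detect import DetectionEvent, Frame, RegionOfInterest
from .session import (
    ApparatusCommand,
    CommandKind,
    EventLog,
    Outcome,
    Phase,
    SessionSchedule,
    TrialRecord,
)

__all__ = [
    "write_events_csv",
    "read_events_csv",
    "write_event_log",
    "read_event_log",
    "load_rois",
    "save_rois",
    "load_schedule",
    "save_schedule",
    "read_frames",
    "save_frames",
]


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _opt_float(s: str) -> float | None:
    return float(s) if s != "" else None


def _opt_int(s: str) -> int | None:
    return int(s) if s != "" else None


# ---------------------------------------------------------------------------
# detection events
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["region", "onset_frame", "offset_frame", "onset_time_s", "offset_time_s"]


def write_events_csv(events: Sequence[DetectionEvent], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(EVENT_COLUMNS)
        for ev in events:
            w.writerow(
                [ev.region, ev.onset_frame, _fmt(ev.offset_frame),
                 _fmt(ev.onset_time), _fmt(ev.offset_time)]
            )
    return path


def read_events_csv(path: str | Path) -> list[DetectionEvent]:
    events = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(EVENT_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"{path}: missing event columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                events.append(
                    DetectionEvent(
                        row["region"],
                        int(row["onset_frame"]),
                        _opt_int(row["offset_frame"]),
                        float(row["onset_time_s"]),
                        _opt_float(row["offset_time_s"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: bad event row {i}: {exc}") from exc
    return events


# ---------------------------------------------------------------------------
# event logs (trials + commands + raw events + metadata)
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = [
    "fish_id", "session", "trial", "stimulus_pos", "outcome", "latency_s",
    "responded_pos", "t_trial_start", "t_psi_start", "t_stim_on",
    "t_stim_off", "t_response", "t_food",
]
COMMAND_COLUMNS = ["time_s", "kind", "arg"]


def write_event_log(log: EventLog, directory: str | Path, stem: str | None = None) -> Path:
    """Write one session log as ``<stem>_{meta.json,trials,events,commands}.csv``.

    Returns the directory.  ``stem`` defaults to ``<fish_id>_s<session_id>``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"{log.fish_id}_s{log.session_id:03d}"

    sched = dataclasses.asdict(log.schedule)
    sched["phase"] = log.schedule.phase.value
    meta = {
        "fish_id": log.fish_id,
        "session_id": log.session_id,
        "schedule": sched,
        "n_reinforcers": log.n_reinforcers,
    }
    (directory / f"{stem}_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    with (directory / f"{stem}_trials.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRIAL_COLUMNS)
        for t in log.trials:
            w.writerow(
                [log.fish_id, log.session_id, t.trial_index,
                 _fmt(t.stimulus_position), t.outcome.value,
                 _fmt(t.response_latency_s), _fmt(t.responded_position),
                 _fmt(t.t_trial_start), _fmt(t.t_psi_start), _fmt(t.t_stim_on),
                 _fmt(t.t_stim_off), _fmt(t.t_response), _fmt(t.t_food)]
            )

    write_events_csv(log.detections, directory / f"{stem}_events.csv")

    with (directory / f"{stem}_commands.csv").open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(COMMAND_COLUMNS)
        for c in log.commands:
            w.writerow([_fmt(c.time_s), c.kind.value, _fmt(c.arg)])
    return directory


def read_event_log(directory: str | Path, stem: str) -> EventLog:
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    sched_dict = dict(meta["schedule"])
    sched_dict["phase"] = Phase(sched_dict["phase"])
    schedule = SessionSchedule(**sched_dict)
    log = EventLog(
        meta["fish_id"], int(meta["session_id"]), schedule,
        n_reinforcers=int(meta["n_reinforcers"]),
    )
    with (directory / f"{stem}_trials.csv").open(newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                log.trials.append(
                    TrialRecord(
                        int(row["trial"]), _opt_int(row["stimulus_pos"]),
                        Outcome(row["outcome"]), _opt_float(row["latency_s"]),
                        _opt_int(row["responded_pos"]),
                        float(row["t_trial_start"]), _opt_float(row["t_psi_start"]),
                        _opt_float(row["t_stim_on"]), _opt_float(row["t_stim_off"]),
                        _opt_float(row["t_response"]), _opt_float(row["t_food"]),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{stem}_trials.csv: bad row {i}: {exc}") from exc
    log.detections = read_events_csv(directory / f"{stem}_events.csv")
    with (directory / f"{stem}_commands.csv").open(newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            log.commands.append(
                ApparatusCommand(float(row["time_s"]), CommandKind(row["kind"]),
                                 _opt_int(row["arg"]))
            )
    return log


def list_log_stems(directory: str | Path) -> list[str]:
    """Stems of all logs in a directory (sorted)."""
    return sorted(
        p.name[: -len("_meta.json")]
        for p in Path(directory).glob("*_meta.json")
    )


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


def _load_structured(path: str | Path) -> object:
    """Parse YAML or JSON config text (YAML is a JSON superset here)."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def load_rois(path: str | Path) -> list[RegionOfInterest]:
    """ROI config: a list of ``{name, rect: [r0, c0, r1, c1], threshold}``."""
    data = _load_structured(path)
    if isinstance(data, dict) and "rois" in data:
        data = data["rois"]
    if not isinstance(data, list):
        raise ValueError(f"{path}: ROI config must be a list of mappings")
    rois = []
    for i, item in enumerate(data):
        try:
            rois.append(
                RegionOfInterest(
                    name=item["name"],
                    rect=tuple(int(v) for v in item["rect"]),
                    threshold=float(item["threshold"]),
                    hysteresis_fraction=float(item.get("hysteresis_fraction", 0.8)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad ROI entry {i}: {exc}") from exc
    return rois


def save_rois(rois: Sequence[RegionOfInterest], path: str | Path) -> Path:
    path = Path(path)
    data = [
        {"name": r.name, "rect": list(r.rect), "threshold": r.threshold,
         "hysteresis_fraction": r.hysteresis_fraction}
        for r in rois
    ]
    path.write_text(yaml.safe_dump({"rois": data}, sort_keys=False))
    return path


def load_schedule(path: str | Path) -> SessionSchedule:
    data = _load_structured(path)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: schedule config must be a mapping")
    return schedule_from_dict(data, source=str(path))


def schedule_from_dict(data: dict, source: str = "schedule") -> SessionSchedule:
    data = dict(data)
    if "phase" in data and not isinstance(data["phase"], Phase):
        try:
            data["phase"] = Phase(str(data["phase"]).upper())
        except ValueError as exc:
            raise ValueError(f"{source}: unknown phase {data['phase']!r}") from exc
    known = {f.name for f in dataclasses.fields(SessionSchedule)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{source}: unknown schedule fields {sorted(unknown)}")
    try:
        return SessionSchedule(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{source}: {exc}") from exc


def save_schedule(schedule: SessionSchedule, path: str | Path) -> Path:
    path = Path(path)
    data = dataclasses.asdict(schedule)
    data["phase"] = schedule.phase.value
    path.write_text(yaml.safe_dump(data, sort_keys=False))
    return path


# ---------------------------------------------------------------------------
# frame I/O
# ---------------------------------------------------------------------------


def read_frames(path: str | Path, fps: float = 50.0) -> list[Frame]:
    """Read a frame sequence from a .npy stack, an image directory, or a
    video/multi-image file readable by imageio."""
    path = Path(path)
    if path.suffix == ".npy":
        arr = np.load(path)
        if arr.ndim not in (3, 4):
            raise ValueError(f"{path}: expected a (n, rows, cols[, ch]) stack")
        return [Frame(arr[i], index=i, fps=fps) for i in range(arr.shape[0])]
    if path.is_dir():
        import imageio.v3 as iio
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in
                       (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"))
        if not files:
            raise ValueError(f"{path}: no image files found")
        return [Frame(iio.imread(f), index=i, fps=fps) for i, f in enumerate(files)]
    import imageio.v3 as iio
    frames = iio.imread(path, index=None)
    return [Frame(frames[i], index=i, fps=fps) for i in range(frames.shape[0])]


def save_frames(frames: Sequence[Frame], path: str | Path) -> Path:
    """Save frames as a single .npy stack (uint8, clipped)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.stack([np.clip(f.pixels, 0, 255) for f in frames]).astype(np.uint8)
    np.save(path, arr)
    return path
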