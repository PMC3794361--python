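"""Presence detection of a fish in small regions of interest (ROIs).

The tank bottom is uniformly bright, so when no fish is present the pixel
intensities inside a small ROI are nearly constant and their variance is
close to zero.  A fish appears as a dark streak (roughly 30 x 5 px at the
nominal 640 x 360 resolution), so its presence inside an ROI raises the
intensity variance by orders of magnitude.  Ambient illumination changes
(shadows, auto-exposure, ripples averaged over the ROI) are approximately
*uniform* across such small regions, and the variance is exactly invariant
under a uniform additive shift -- which is why variance, not mean intensity
or background subtraction, is the detection statistic.

Detection is debounced with a Schmitt trigger: a fish is detected when the
variance exceeds an operator-set threshold ``T`` and is deemed to have left
only when the variance falls below ``0.8 * T``.  No new detection can be
triggered until that release has happened, which suppresses chatter when
the variance hovers near the threshold.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Frame",
    "RoiState",
    "Edge",
    "RegionOfInterest",
    "DetectionEvent",
    "SyntheticSceneParams",
    "roi_variance",
    "schmitt_update",
    "process_stream",
    "suggest_threshold",
    "make_synthetic_video",
    "iter_synthetic_video",
    "waypoint_trajectory",
]

DEFAULT_FPS = 50.0


class RoiState(enum.Enum):
    VACANT = "VACANT"
    OCCUPIED = "OCCUPIED"


class Edge(enum.Enum):
    NONE = "NONE"
    ONSET = "ONSET"
    OFFSET = "OFFSET"


@dataclass(frozen=True)
class Frame:
    """A single grayscale video frame.

    ``pixels`` is a 2-D array of intensities, nominally in [0, 255] (the
    range is not enforced so that arithmetic on frames, e.g. adding a
    uniform illumination offset, stays exact).  ``time`` of the frame is
    ``index / fps``.
    """

    pixels: np.ndarray
    index: int = 0
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim == 3:
            # color input: unweighted channel mean (the rig camera is B/W;
            # color only ever arrives from fixture files)
            px = px.mean(axis=2)
        if px.ndim != 2:
            raise ValueError(f"frame must be 2-D grayscale, got ndim={px.ndim}")
        if self.index < 0:
            raise ValueError("frame index must be nonnegative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def time(self) -> float:
        return self.index / self.fps

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class RegionOfInterest:
    """Named rectangular pixel region with a detection threshold.

    ``rect`` is (row0, col0, row1, col1), 0-based, half-open.  ``threshold``
    is the variance level above which a fish is detected; release happens
    below ``hysteresis_fraction * threshold``.
    """

    name: str
    rect: tuple[int, int, int, int]
    threshold: float
    hysteresis_fraction: float = 0.8
    state: RoiState = RoiState.VACANT

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.rect
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"ROI {self.name!r}: empty rect {self.rect}")
        if (r1 - r0) * (c1 - c0) < 2:
            raise ValueError(f"ROI {self.name!r}: must contain >= 2 pixels")
        if self.threshold <= 0:
            raise ValueError(f"ROI {self.name!r}: threshold must be > 0")
        if not 0 < self.hysteresis_fraction < 1:
            raise ValueError("hysteresis_fraction must be in (0, 1)")

    @property
    def n_pixels(self) -> int:
        r0, c0, r1, c1 = self.rect
        return (r1 - r0) * (c1 - c0)

    @property
    def center(self) -> tuple[float, float]:
        r0, c0, r1, c1 = self.rect
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


@dataclass(frozen=True)
class DetectionEvent:
    """One contiguous occupancy of a region: onset edge to offset edge.

    ``offset_frame``/``offset_time`` are ``None`` while the occupancy is
    still open at the end of the stream.
    """

    region: str
    onset_frame: int
    offset_frame: int | None
    onset_time: float
    offset_time: float | None

    def __post_init__(self) -> None:
        if self.offset_frame is not None and self.offset_frame < self.onset_frame:
            raise ValueError("offset_frame must be >= onset_frame")


def roi_variance(frame: Frame, roi: RegionOfInterest) -> float:
    """Population variance of the pixel intensities inside ``roi.rect``.

    Exactly 0 for a constant region; exactly invariant under a uniform
    additive intensity shift.  Raises if the ROI falls outside the frame.
    """
    r0, c0, r1, c1 = roi.rect
    nrow, ncol = frame.shape
    if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
        raise ValueError(
            f"ROI {roi.name!r} rect {roi.rect} outside frame of shape {frame.shape}"
        )
    patch = frame.pixels[r0:r1, c0:c1]
    return float(np.var(patch))


def schmitt_update(
    roi: RegionOfInterest, variance: float
) -> tuple[RegionOfInterest, Edge]:
    """One step of the two-threshold hysteresis switch.

    VACANT and variance > T          -> OCCUPIED, ONSET
    OCCUPIED and variance < 0.8 T    -> VACANT,   OFFSET
    otherwise                        -> unchanged, NONE

    Boundary values (exactly T, exactly 0.8 T) do not transition.  While
    OCCUPIED no new onset can fire; the variance must first fall below the
    release level.
    """
    if roi.state is RoiState.VACANT:
        if variance > roi.threshold:
            return replace(roi, state=RoiState.OCCUPIED), Edge.ONSET
    else:
        if variance < roi.hysteresis_fraction * roi.threshold:
            return replace(roi, state=RoiState.VACANT), Edge.OFFSET
    return roi, Edge.NONE


def process_stream(
    frames: Iterable[Frame], rois: Sequence[RegionOfInterest]
) -> list[DetectionEvent]:
    """Run the variance detector over a frame stream for every ROI.

    Returns per-region, non-overlapping detection events ordered by onset
    frame (ties broken by region name).  Every ROI starts VACANT.  An
    occupancy still open when the stream ends is emitted with a ``None``
    offset.
    """
    states = {roi.name: replace(roi, state=RoiState.VACANT) for roi in rois}
    open_onsets: dict[str, tuple[int, float]] = {}
    events: list[DetectionEvent] = []
    shape: tuple[int, int] | None = None

    for frame in frames:
        if shape is None:
            shape = frame.shape
        elif frame.shape != shape:
            raise ValueError(
                f"inconsistent frame dimensions: {frame.shape} vs {shape}"
            )
        for name, roi in states.items():
            v = roi_variance(frame, roi)
            roi, edge = schmitt_update(roi, v)
            states[name] = roi
            if edge is Edge.ONSET:
                open_onsets[name] = (frame.index, frame.time)
            elif edge is Edge.OFFSET:
                onset_frame, onset_time = open_onsets.pop(name)
                events.append(
                    DetectionEvent(name, onset_frame, frame.index, onset_time, frame.time)
                )

    for name, (onset_frame, onset_time) in open_onsets.items():
        events.append(DetectionEvent(name, onset_frame, None, onset_time, None))

    events.sort(key=lambda e: (e.onset_frame, e.region))
    return events


def suggest_threshold(
    variance_trace: Sequence[float], vacant_fraction: float = 0.9
) -> float:
    """Offline replacement for interactive threshold setting.

    Assumes at least ``vacant_fraction`` of the trace was recorded with the
    region vacant.  Returns a threshold halfway between the
    ``vacant_fraction`` quantile (an upper bound on vacant-state variance)
    and the trace maximum, which places the hysteresis release level
    (``0.8 T``) comfortably above vacant noise for well-separated traces.
    """
    trace = np.asarray(variance_trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("empty variance trace")
    if not 0 < vacant_fraction < 1:
        raise ValueError("vacant_fraction must be in (0, 1)")
    q = float(np.quantile(trace, vacant_fraction))
    hi = float(trace.max())
    if hi <= q or math.isclose(hi, q, rel_tol=1e-12):
        raise ValueError(
            "degenerate variance trace (no separation between vacant and "
            "occupied levels); set the threshold manually"
        )
    return q + 0.5 * (hi - q)


# ---------------------------------------------------------------------------
# synthetic scene generator
# ---------------------------------------------------------------------------

Trajectory = Callable[[int], tuple[float, float] | None]


@dataclass(frozen=True)
class SyntheticSceneParams:
    """Parameters of the synthetic tank scene used for fixture videos.

    The scene emulates the rig's imaging conditions: a uniformly bright
    background, global (spatially uniform) illumination fluctuations, pixel
    ripple noise, and the fish as a dark streak of ``fish_length_px`` x
    ``fish_width_px`` (defaults 30 x 5, horizontal).  ``trajectory`` maps a
    frame index to the fish centre ``(row, col)`` or ``None`` when the fish
    is absent (out of every ROI's sight).  The same seed always produces a
    bit-identical frame sequence.
    """

    frame_shape: tuple[int, int] = (360, 640)
    background_level: float = 220.0
    illumination_drift: Sequence[float] | float = 0.0
    ripple_sigma: float = 0.0
    fish_length_px: int = 30
    fish_width_px: int = 5
    fish_intensity: float = 40.0
    trajectory: Trajectory | None = None
    fps: float = DEFAULT_FPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fish_intensity >= self.background_level:
            raise ValueError("fish must be darker than the background")
        if self.ripple_sigma < 0:
            raise ValueError("ripple_sigma must be >= 0")
        if self.fish_length_px < 1 or self.fish_width_px < 1:
            raise ValueError("fish dimensions must be >= 1 px")

    def drift_at(self, index: int) -> float:
        d = self.illumination_drift
        if np.isscalar(d):
            return float(d)  # type: ignore[arg-type]
        seq = np.asarray(d, dtype=np.float64)
        return float(seq[index]) if index < seq.size else float(seq[-1])


def waypoint_trajectory(
    waypoints: Sequence[tuple[int, float | None, float | None]],
) -> Trajectory:
    """Build a step trajectory from ``(frame, row, col)`` waypoints.

    Between waypoints the fish holds the most recent position; ``(frame,
    None, None)`` marks the fish leaving the field of view.  Before the
    first waypoint the fish is absent.
    """
    pts = sorted(waypoints, key=lambda w: w[0])

    def traj(index: int) -> tuple[float, float] | None:
        pos: tuple[float, float] | None = None
        for f, r, c in pts:
            if f > index:
                break
            pos = None if r is None else (float(r), float(c))
        return pos

    return traj


def _render_fish(
    pixels: np.ndarray, center: tuple[float, float], params: SyntheticSceneParams
) -> None:
    """Stamp the dark streak onto ``pixels`` in place (clipped to frame)."""
    nrow, ncol = pixels.shape
    r, c = center
    h, w = params.fish_width_px, params.fish_length_px  # horizontal streak
    r0 = int(round(r - h / 2.0))
    c0 = int(round(c - w / 2.0))
    r1, c1 = r0 + h, c0 + w
    if r0 < 0 or c0 < 0 or r1 > nrow or c1 > ncol:
        raise ValueError(
            f"fish at {center} (streak {h}x{w}) extends outside frame {pixels.shape}"
        )
    pixels[r0:r1, c0:c1] = params.fish_intensity


def iter_synthetic_video(params: SyntheticSceneParams, n_frames: int):
    """Yield the synthetic frame sequence one frame at a time.

    Per frame: flat background + uniform illumination offset + i.i.d.
    Gaussian ripple noise, with the fish streak stamped at the trajectory
    position, clipped to [0, 255].  Streaming keeps long fixtures at
    constant memory; the generated sequence is identical to
    ``make_synthetic_video``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(params.seed)
    for i in range(n_frames):
        px = np.full(params.frame_shape, params.background_level, dtype=np.float64)
        px += params.drift_at(i)
        if params.ripple_sigma > 0:
            px += rng.normal(0.0, params.ripple_sigma, size=params.frame_shape)
        if params.trajectory is not None:
            pos = params.trajectory(i)
            if pos is not None:
                _render_fish(px, pos, params)
        np.clip(px, 0.0, 255.0, out=px)
        yield Frame(px, index=i, fps=params.fps)


def make_synthetic_video(
    params: SyntheticSceneParams, n_frames: int
) -> list[Frame]:
    """Render a reproducible synthetic frame sequence (materialized list)."""
    return list(iter_synthetic_video(params, n_frames))
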