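"""Shared fixtures: scripted high-contrast scenes and event builders."""

from __future__ import annotations

import numpy as np
import pytest

from fishrig.detect import (
    RegionOfInterest,
    SyntheticSceneParams,
    make_synthetic_video,
    waypoint_trajectory,
)


@pytest.fixture(scope="session")
def magazine_roi() -> RegionOfInterest:
    return RegionOfInterest("magazine", (10, 30, 60, 100), threshold=200.0)


@pytest.fixture(scope="session")
def scripted_scene(magazine_roi):
    """High-contrast fixture: fish enters the magazine ROI at frame 100,
    leaves at frame 180, with mild ripple noise and slow illumination drift."""
    n_frames = 250
    drift = 5.0 * np.sin(np.linspace(0, 2 * np.pi, n_frames))
    params = SyntheticSceneParams(
        frame_shape=(120, 400),
        background_level=180.0,
        illumination_drift=drift,
        ripple_sigma=1.0,
        trajectory=waypoint_trajectory([(100, 35, 65), (180, None, None)]),
        seed=12345,
    )
    frames = make_synthetic_video(params, n_frames)
    return params, frames


def make_entry_events(times_by_region, fps: float = 50.0, dwell: float = 0.5):
    """Detection events (onset at the given times, fixed dwell) in time order."""
    from fishrig.detect import DetectionEvent

    items = []
    for region, times in times_by_region.items():
        for t in times:
            f_on = round(t * fps)
            f_off = f_on + max(1, round(dwell * fps))
            items.append(DetectionEvent(region, f_on, f_off, f_on / fps, f_off / fps))
    items.sort(key=lambda e: e.onset_time)
    return items
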