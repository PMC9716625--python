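"""Shared fixtures: tiny duo recordings and a session-scoped miniature study."""

from __future__ import annotations

import numpy as np
import pytest

from duetsense.io import DuoRecording, MarkerTrajectory
from duetsense.pipeline import analyze_study
from duetsense.simulate import generate_study, miniature_config


def build_duo(
    markers: dict[str, np.ndarray],
    group: str = "piano",
    rate: float = 240.0,
    stimulus_id: str = "piano_01",
) -> DuoRecording:
    """A DuoRecording from raw (n, 3) position arrays keyed by marker id."""
    return DuoRecording(
        stimulus_id=stimulus_id,
        stimulus_group=group,
        trajectories={
            mid: MarkerTrajectory(mid, xyz, rate) for mid, xyz in markers.items()
        },
    )


def constant_velocity_marker(
    v: tuple[float, float, float], n: int, rate: float = 240.0
) -> np.ndarray:
    t = np.arange(n)[:, None] / rate
    return t * np.asarray(v, dtype=float)


@pytest.fixture(scope="session")
def mini_study_dir(tmp_path_factory):
    """A generated miniature synthetic study bundle (seed 11)."""
    path = tmp_path_factory.mktemp("study") / "bundle"
    generate_study(miniature_config(seed=11), path)
    return path


@pytest.fixture(scope="session")
def mini_analysis(mini_study_dir):
    """Full pipeline analysis of the miniature study."""
    return analyze_study(mini_study_dir, k=6, seed=11)
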