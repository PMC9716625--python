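"""Trajectory smoothing, differentiation and quantity of motion (QoM).

QoM summarises how much a duo moves: per-marker speeds (Euclidean norm of the
Savitzky-Golay velocity) are summed over markers within each musician and
averaged across the two musicians ("total" scope), or averaged across the duo
for a single paired marker ("local" scope).  Feature series are block-averaged
down to the 10 Hz grid of the rating stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .io import DuoRecording, MarkerTrajectory

__all__ = [
    "KinematicSeries",
    "smooth_and_differentiate",
    "marker_speed",
    "block_average",
    "quantity_of_motion",
    "grand_mean_qom",
]

_KIND_BY_ORDER = {0: "position", 1: "velocity", 2: "acceleration"}
_UNITS_BY_ORDER = {0: "mm", 1: "mm/s", 2: "mm/s^2"}


@dataclass
class KinematicSeries:
    """A uniformly sampled kinematic quantity (scalar or 3-vector samples)."""

    kind: str  # position | velocity | acceleration | speed | qom
    values: np.ndarray
    rate: float
    units: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.kind in ("speed", "qom") and np.any(self.values < -1e-12):
            raise ValueError(f"{self.kind} values must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


def smooth_and_differentiate(
    traj: MarkerTrajectory,
    window: int = 25,
    polyorder: int = 2,
    order: int = 0,
) -> KinematicSeries:
    """Savitzky-Golay smoothing/differentiation of a marker trajectory.

    ``order`` 0 returns the smoothed position (mm), 1 the velocity (mm/s)
    and 2 the acceleration (mm/s^2); derivatives are scaled by the sampling
    rate.  The filter is same-length (no samples are lost); the default
    25-frame window at 240 Hz spans ~104 ms.
    """
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > traj.n_samples:
        raise ValueError(
            f"window {window} exceeds trajectory length {traj.n_samples}"
        )
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    values = savgol_filter(
        traj.positions, window, polyorder, deriv=order, delta=1.0 / traj.rate, axis=0
    )
    return KinematicSeries(
        _KIND_BY_ORDER[order], values, traj.rate, _UNITS_BY_ORDER[order]
    )


def marker_speed(vel: KinematicSeries) -> KinematicSeries:
    """Per-sample Euclidean norm of a 3-D velocity series (mm/s)."""
    if vel.kind != "velocity":
        raise ValueError(f"expected a velocity series, got {vel.kind!r}")
    if vel.values.ndim != 2 or vel.values.shape[1] != 3:
        raise ValueError("velocity series must hold 3-vectors")
    return KinematicSeries(
        "speed", np.linalg.norm(vel.values, axis=1), vel.rate, "mm/s"
    )


def block_average(values: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    """Resample by averaging consecutive non-overlapping blocks.

    ``out_rate`` must divide ``in_rate``; trailing samples not filling a whole
    block are dropped.  The mean of the output equals the mean of the retained
    input to float precision.
    """
    ratio = in_rate / out_rate
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"out_rate {out_rate} must divide in_rate {in_rate}")
    factor = int(round(ratio))
    if factor == 1:
        return np.asarray(values, dtype=float).copy()
    values = np.asarray(values, dtype=float)
    n_blocks = values.shape[0] // factor
    trimmed = values[: n_blocks * factor]
    return trimmed.reshape(n_blocks, factor, *values.shape[1:]).mean(axis=1)


def _marker_speeds(
    rec: DuoRecording,
    role: str,
    marker_ids: list[str],
    window: int,
    polyorder: int,
) -> np.ndarray:
    """(n_samples, n_markers) speed array for one musician's markers."""
    cols = []
    for mid in marker_ids:
        vel = smooth_and_differentiate(
            rec.trajectories[mid], window=window, polyorder=polyorder, order=1
        )
        cols.append(marker_speed(vel).values)
    return np.column_stack(cols)


def quantity_of_motion(
    rec: DuoRecording,
    scope: str = "total",
    markers: list[str] | None = None,
    out_rate: float | None = 10.0,
    window: int = 25,
    polyorder: int = 2,
) -> KinematicSeries:
    """Quantity of motion of a duo recording.

    ``scope="total"``: marker speeds are summed across markers per musician at
    each timestamp, then averaged across the two musicians.  Clarinet
    recordings include the instrument markers; piano recordings do not (the
    keyboards do not move).  ``scope="local"``: ``markers`` names exactly one
    paired body part (e.g. ``"head"``) and the duo mean of that marker's speed
    is returned.  ``out_rate=None`` keeps the native rate.
    """
    include_inst = rec.stimulus_group == "clarinet"
    per_musician = []
    for role in ("P", "S"):
        if scope == "total":
            ids = rec.markers_for(role, include_instruments=include_inst)
            if markers is not None:
                ids = [m for m in ids if m.split("_", 1)[1] in markers]
        elif scope == "local":
            if not markers or len(markers) != 1:
                raise ValueError("local scope needs exactly one body part name")
            ids = [f"{role}_{markers[0]}"]
        else:
            raise ValueError(f"unknown scope {scope!r}")
        missing = [m for m in ids if m not in rec.trajectories]
        if missing or not ids:
            raise ValueError(
                f"markers missing for musician {role}: {missing or markers}"
            )
        speeds = _marker_speeds(rec, role, ids, window, polyorder)
        if scope == "total":
            per_musician.append(speeds.sum(axis=1))
        else:
            per_musician.append(speeds[:, 0])
    qom = np.mean(per_musician, axis=0)
    rate = rec.rate
    if out_rate is not None:
        qom = block_average(qom, rate, out_rate)
        rate = out_rate
    return KinematicSeries("qom", qom, rate, "mm/s")


def grand_mean_qom(
    rec: DuoRecording, window: int = 25, polyorder: int = 2
) -> float:
    """Grand mean of the duo's summed velocities (mm/s), one scalar per
    recording; used to characterise stimuli by overall movement energy.

    The native-rate total QoM series is averaged within non-overlapping 1 s
    bins aligned to t=0, then averaged across bins.
    """
    if rec.duration < 1.0:
        raise ValueError("recording shorter than 1 s")
    total = quantity_of_motion(
        rec, scope="total", out_rate=None, window=window, polyorder=polyorder
    )
    per_second = block_average(total.values, rec.rate, 1.0)
    return float(per_second.mean())
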