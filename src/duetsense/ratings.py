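"""Continuous togetherness ratings: densification, lag alignment, exclusions.

Slider logs are sparse: a (t, value) row exists only when the participant
moved the slider.  ``densify`` reconstructs the evenly sampled 10 Hz series
by previous-value (constant) interpolation, with the slider-center value
before the first event (the handle starts at the centre of the scale).
Ratings are then aligned with stimulus features at a perceptual lag: the
response at time ``t + lag`` is paired with the features at ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SLIDER_CENTER, NoteEvent, SliderEventStream

__all__ = [
    "RatingSeries",
    "densify",
    "exclude_trials",
    "lag_align",
    "sync_reference_ratings",
    "log_offset",
    "log_transform",
]

CANDIDATE_LAGS = (1.0, 2.0, 3.0)


@dataclass
class RatingSeries:
    """Dense 10 Hz togetherness rating series of one trial."""

    participant_id: str
    stimulus_id: str
    modality: str
    values: np.ndarray  # 0-100 at `rate`
    rate: float = 10.0
    lag_applied: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > 100):
            raise ValueError("rating values outside slider bounds")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate


def densify(
    stream: SliderEventStream,
    duration: float,
    rate: float = 10.0,
    initial: float = SLIDER_CENTER,
) -> RatingSeries:
    """Previous-value interpolation of a sparse slider stream onto a 10 Hz grid.

    Grid samples sit at t = 0.0, 0.1, ...; an event at exactly a grid time
    takes effect at that sample.  Samples before the first event hold
    ``initial`` (the slider centre).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * rate))
    grid = np.arange(n) / rate
    events = stream.events
    if len(events) == 0:
        values = np.full(n, float(initial))
    else:
        # index of the last event with time <= grid point (-1: before first)
        idx = np.searchsorted(events[:, 0], grid + 1e-9, side="right") - 1
        values = np.where(idx >= 0, events[np.clip(idx, 0, None), 1], initial)
    return RatingSeries(
        stream.participant_id, stream.stimulus_id, stream.modality, values, rate
    )


def exclude_trials(
    streams: list[SliderEventStream],
) -> tuple[list[SliderEventStream], dict[str, int]]:
    """Drop partial trials and second presentations of repeated stimuli.

    Returns the retained streams and a report counting exclusions by reason.
    Streams in which the participant never moved the slider are retained
    (a flat rating at the centre is a valid response).
    """
    kept = []
    report = {"partial": 0, "repeat": 0, "retained": 0, "no_change": 0}
    for s in streams:
        if s.trial_status == "partial":
            report["partial"] += 1
        elif s.trial_status == "repeat":
            report["repeat"] += 1
        else:
            if s.trial_status == "no_change":
                report["no_change"] += 1
            report["retained"] += 1
            kept.append(s)
    return kept, report


def lag_align(
    series: RatingSeries,
    features: pd.DataFrame,
    lag: float,
    allow_any_lag: bool = False,
) -> pd.DataFrame:
    """Pair the response at ``t + lag`` with the predictors at ``t``.

    ``features`` holds one row per 10 Hz step with a ``t`` column and one
    column per predictor.  The trailing ``lag`` seconds (for which no lagged
    response exists) are dropped.  ``lag`` must be one of the candidate
    perceptual lags (1, 2, 3 s) unless ``allow_any_lag``.
    """
    if not allow_any_lag and lag not in CANDIDATE_LAGS:
        raise ValueError(f"lag {lag} outside candidate set {CANDIDATE_LAGS}")
    rate = series.rate
    shift = lag * rate
    if abs(shift - round(shift)) > 1e-9:
        raise ValueError(f"lag {lag} not a multiple of the 10 Hz step")
    shift = int(round(shift))
    n_resp = len(series.values)
    n_feat = len(features)
    # Truncate to the shorter of stimulus/response durations (sub-150 ms
    # recording discrepancies are absorbed here).
    n = min(n_feat, n_resp - shift)
    if n <= 0:
        raise ValueError("lag equals or exceeds series duration")
    out = features.iloc[:n].copy().reset_index(drop=True)
    out.insert(0, "response", series.values[shift : shift + n])
    out.insert(0, "modality", series.modality)
    out.insert(0, "stimulus", series.stimulus_id)
    out.insert(0, "participant", series.participant_id)
    out["lag"] = lag
    return out


def sync_reference_ratings(
    series: RatingSeries,
    events: list[NoteEvent],
    lag: float,
) -> tuple[pd.DataFrame, int]:
    """Rating value lagging each synchronization point by ``lag`` seconds.

    The reference time of a sync point is the latest onset among both parts
    (for chords, the latest chord-member onset).  The response is read at the
    nearest 10 Hz sample of ``reference + lag``; points overshooting the end
    of the series are dropped and counted.
    """
    refs: dict[int, float] = {}
    for e in events:
        refs[e.sync_index] = max(refs.get(e.sync_index, -np.inf), e.onset)
    rows = []
    dropped = 0
    for sync_index in sorted(refs):
        t = refs[sync_index] + lag
        idx = int(round(t * series.rate))
        if idx >= len(series.values):
            dropped += 1
            continue
        rows.append(
            {
                "participant": series.participant_id,
                "stimulus": series.stimulus_id,
                "modality": series.modality,
                "sync_index": sync_index,
                "reference_t": refs[sync_index],
                "response": series.values[idx],
            }
        )
    return pd.DataFrame(rows), dropped


def log_offset(values: np.ndarray) -> float:
    """Offset for log-transforming a non-negative skewed predictor.

    Uses the smallest positive observed value times 1e-3, so zeros (silent or
    motionless frames) map to a finite value well below the observed range.
    """
    values = np.asarray(values, dtype=float)
    positive = values[values > 0]
    if len(positive) == 0:
        raise ValueError("predictor has no positive values")
    return float(positive.min() * 1e-3)


def log_transform(
    table: pd.DataFrame, columns: list[str], eps: dict[str, float] | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Return a copy with ``log(x + eps)`` applied to ``columns``.

    One offset per column, computed from the pooled column values unless
    supplied; offsets are returned for the run manifest.
    """
    out = table.copy()
    used: dict[str, float] = {}
    for col in columns:
        e = (eps or {}).get(col)
        if e is None:
            e = log_offset(out[col].to_numpy())
        used[col] = e
        out[col] = np.log(out[col].to_numpy(float) + e)
    return out, used
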