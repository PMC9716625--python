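"""Readers and writers for the on-disk formats the pipeline touches.

All tabular formats are plain CSV/TSV with a header row, UTF-8, ``.`` decimal.
Time columns are seconds as decimal floats; marker coordinates are millimetres
(the OptiTrack convention), so quantity-of-motion magnitudes are comparable
across recordings.
"""

from __future__ import annotations

import struct
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerTrajectory",
    "DuoRecording",
    "NoteEvent",
    "SliderEventStream",
    "BODY_PARTS",
    "COORDINATION_PARTS",
    "MODALITIES",
    "read_marker_trajectories",
    "write_marker_trajectories",
    "read_note_events",
    "write_note_events",
    "read_smf_note_onsets",
    "read_slider_events",
    "write_slider_events",
]

#: Body parts tracked on each musician.  Hands are tracked but excluded from
#: the coordination analysis (hand motion is dictated by sound production).
BODY_PARTS = (
    "head",
    "chest",
    "l_shoulder",
    "r_shoulder",
    "l_arm",
    "r_arm",
    "l_hand",
    "r_hand",
)

#: The six paired body parts entering the cross-wavelet coordination analysis.
COORDINATION_PARTS = ("head", "chest", "l_shoulder", "r_shoulder", "l_arm", "r_arm")

MODALITIES = ("AO", "VO", "AV")

ROLES = ("P", "S")  # Primo, Secondo

SLIDER_MIN, SLIDER_MAX, SLIDER_CENTER = 0.0, 100.0, 50.0


@dataclass
class MarkerTrajectory:
    """Uniformly sampled 3-D positions (mm) of one reflective marker.

    ``marker_id`` encodes musician role and body part, e.g. ``"P_head"`` or
    ``"S_l_arm"``; instrument markers use ``"P_inst1"`` style ids.
    """

    marker_id: str
    positions: np.ndarray  # (n, 3) mm
    rate: float  # Hz

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError(f"positions must be (n, 3), got {self.positions.shape}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"non-finite coordinates in marker {self.marker_id!r}")

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def role(self) -> str:
        return self.marker_id.split("_", 1)[0]

    @property
    def body_part(self) -> str:
        return self.marker_id.split("_", 1)[1]


@dataclass
class NoteEvent:
    """One score-notated synchronization point onset for one duo part."""

    part: str  # "P" or "S"
    sync_index: int  # 1..N ordinal of the sync point
    onset: float  # s
    chord_group: int | None = None

    def __post_init__(self) -> None:
        if self.part not in ROLES:
            raise ValueError(f"part must be one of {ROLES}, got {self.part!r}")
        if self.onset < 0:
            raise ValueError(f"negative onset {self.onset} for part {self.part}")


@dataclass
class DuoRecording:
    """One duo stimulus: paired marker trajectories plus optional note events
    and audio-derived intensity."""

    stimulus_id: str
    stimulus_group: str  # "piano" | "clarinet"
    trajectories: dict[str, MarkerTrajectory]
    note_events: list[NoteEvent] = field(default_factory=list)
    intensity: object | None = None  # audio.IntensityEnvelope
    audio: tuple[np.ndarray, int] | None = None  # (samples, rate)

    def __post_init__(self) -> None:
        if self.stimulus_group not in ("piano", "clarinet"):
            raise ValueError(f"unknown stimulus group {self.stimulus_group!r}")
        roles = {t.role for t in self.trajectories.values()}
        if not {"P", "S"} <= roles:
            raise ValueError("both musicians (P and S) must have trajectories")
        rates = {t.rate for t in self.trajectories.values()}
        lengths = {t.n_samples for t in self.trajectories.values()}
        if len(rates) > 1 or len(lengths) > 1:
            raise ValueError("all trajectories must share rate and duration")

    @property
    def rate(self) -> float:
        return next(iter(self.trajectories.values())).rate

    @property
    def n_samples(self) -> int:
        return next(iter(self.trajectories.values())).n_samples

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def markers_for(self, role: str, include_instruments: bool = False) -> list[str]:
        """Marker ids belonging to one musician, sorted for determinism."""
        out = []
        for mid, traj in self.trajectories.items():
            if traj.role != role:
                continue
            if not include_instruments and traj.body_part.startswith("inst"):
                continue
            out.append(mid)
        return sorted(out)


@dataclass
class SliderEventStream:
    """Sparse slider log of one participant x stimulus x modality trial.

    ``events`` holds (t, value) rows only at the instants the participant
    moved the slider; the value before the first event is the slider center.
    """

    participant_id: str
    stimulus_id: str
    modality: str
    events: np.ndarray  # (n, 2): t s, value 0-100
    trial_status: str = "complete"  # complete | partial | repeat | no_change

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        self.events = np.asarray(self.events, dtype=float).reshape(-1, 2)
        if len(self.events):
            t, v = self.events[:, 0], self.events[:, 1]
            if np.any(np.diff(t) <= 0):
                raise ValueError("event times must be strictly increasing")
            if t[0] < 0:
                raise ValueError("event before t=0")
            if np.any(v < SLIDER_MIN) or np.any(v > SLIDER_MAX):
                raise ValueError("slider value outside bounds")
        elif self.trial_status == "complete":
            self.trial_status = "no_change"

    @property
    def trial_key(self) -> tuple[str, str, str]:
        return (self.participant_id, self.stimulus_id, self.modality)


# ---------------------------------------------------------------------------
# Marker trajectories
# ---------------------------------------------------------------------------


def read_marker_trajectories(
    path: str | Path,
    rate: float,
    max_gap: int = 12,
    grid_tol: float = 1e-4,
) -> dict[str, MarkerTrajectory]:
    """Read a wide marker table (columns ``time, <marker>_x, _y, _z``).

    Runs of up to ``max_gap`` consecutive missing samples (~50 ms at 240 Hz by
    default) are filled by linear interpolation; longer gaps are rejected, as
    is an all-missing marker or a non-uniform time grid.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if "time" not in df.columns:
        raise ValueError("missing 'time' column")
    t = df["time"].to_numpy(float)
    dt = 1.0 / rate
    if len(t) > 1 and np.max(np.abs(np.diff(t) - dt)) > grid_tol:
        raise ValueError("non-uniform time grid beyond tolerance")

    markers: dict[str, MarkerTrajectory] = {}
    axis_cols = [c for c in df.columns if c.endswith(("_x", "_y", "_z"))]
    ids = sorted({c[:-2] for c in axis_cols})
    if not ids:
        raise ValueError("no marker coordinate columns found")
    for mid in ids:
        cols = [f"{mid}_{ax}" for ax in "xyz"]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"marker {mid!r} missing columns {missing}")
        xyz = df[cols].to_numpy(float)
        nan_rows = np.any(~np.isfinite(xyz), axis=1)
        if nan_rows.all():
            raise ValueError(f"marker {mid!r} is all-NaN")
        if nan_rows.any():
            xyz = _interpolate_gaps(xyz, nan_rows, max_gap, mid)
        markers[mid] = MarkerTrajectory(mid, xyz, rate)
    return markers


def _interpolate_gaps(
    xyz: np.ndarray, nan_rows: np.ndarray, max_gap: int, mid: str
) -> np.ndarray:
    """Linearly fill NaN runs of length <= max_gap; reject longer runs."""
    idx = np.arange(len(xyz))
    runs = _nan_runs(nan_rows)
    for start, stop in runs:
        if stop - start > max_gap:
            raise ValueError(
                f"gap too long in marker {mid!r}: {stop - start} samples "
                f"(max_gap={max_gap})"
            )
        if start == 0 or stop == len(xyz):
            raise ValueError(f"marker {mid!r} missing at series edge")
    out = xyz.copy()
    good = ~nan_rows
    for ax in range(3):
        out[nan_rows, ax] = np.interp(idx[nan_rows], idx[good], xyz[good, ax])
    return out


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    in_run = False
    start = 0
    for i, m in enumerate(mask):
        if m and not in_run:
            in_run, start = True, i
        elif not m and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(mask)))
    return runs


def write_marker_trajectories(
    path: str | Path, markers: dict[str, MarkerTrajectory]
) -> None:
    """Write markers as a wide CSV (inverse of :func:`read_marker_trajectories`)."""
    first = next(iter(markers.values()))
    t = np.arange(first.n_samples) / first.rate
    data = {"time": t}
    for mid in sorted(markers):
        for k, ax in enumerate("xyz"):
            data[f"{mid}_{ax}"] = markers[mid].positions[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Note events
# ---------------------------------------------------------------------------


def read_note_events(path: str | Path) -> list[NoteEvent]:
    """Read sync-point note events from CSV
    (columns ``part, sync_index, onset_s, chord_group``)."""
    df = pd.read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty note-event file", stacklevel=2)
        return []
    required = {"part", "sync_index", "onset_s"}
    if not required <= set(df.columns):
        raise ValueError(f"note-event CSV needs columns {sorted(required)}")
    events = []
    for row in df.itertuples(index=False):
        chord = getattr(row, "chord_group", None)
        if chord is not None and (pd.isna(chord) or chord == ""):
            chord = None
        events.append(
            NoteEvent(
                part=str(row.part),
                sync_index=int(row.sync_index),
                onset=float(row.onset_s),
                chord_group=None if chord is None else int(chord),
            )
        )
    _validate_sync_points(events)
    events.sort(key=lambda e: (e.part, e.onset))
    return events


def _validate_sync_points(events: Sequence[NoteEvent]) -> None:
    by_part: dict[str, set[int]] = {"P": set(), "S": set()}
    for e in events:
        by_part[e.part].add(e.sync_index)
    only_p = by_part["P"] - by_part["S"]
    only_s = by_part["S"] - by_part["P"]
    if only_p or only_s:
        raise ValueError(
            f"sync_index present in only one part: P-only={sorted(only_p)}, "
            f"S-only={sorted(only_s)}"
        )


def write_note_events(path: str | Path, events: Iterable[NoteEvent]) -> None:
    rows = [
        {
            "part": e.part,
            "sync_index": e.sync_index,
            "onset_s": e.onset,
            "chord_group": "" if e.chord_group is None else e.chord_group,
        }
        for e in events
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Standard MIDI File (thin adapter)
# ---------------------------------------------------------------------------


def read_smf_note_onsets(path: str | Path) -> pd.DataFrame:
    """Extract note-on times from a format 0/1 Standard MIDI File.

    Thin adapter: returns a frame with ``track, onset_s, pitch, velocity``
    rows sorted by onset.  Mapping tracks to duo parts and picking the
    annotated sync notes is the caller's job (see :func:`annotate_sync_notes`).
    Sustain and note-off information is ignored.
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"MThd":
        raise ValueError("not a Standard MIDI File (missing MThd)")
    hlen, fmt, ntrk, division = struct.unpack(">IHHH", raw[4:14])
    if division & 0x8000:
        raise ValueError("SMPTE time division not supported")
    pos = 8 + hlen
    tracks: list[list[tuple[int, int, int, int]]] = []  # (tick, kind, pitch, vel)
    tempo_changes: list[tuple[int, int]] = [(0, 500000)]  # (tick, us per quarter)
    for itrk in range(ntrk):
        if raw[pos : pos + 4] != b"MTrk":
            raise ValueError("malformed SMF: missing MTrk chunk")
        tlen = struct.unpack(">I", raw[pos + 4 : pos + 8])[0]
        data = raw[pos + 8 : pos + 8 + tlen]
        pos += 8 + tlen
        tracks.append(_parse_track(data, tempo_changes))
    tempo_changes.sort()
    rows = []
    for itrk, evs in enumerate(tracks):
        for tick, pitch, vel in evs:
            rows.append(
                {
                    "track": itrk,
                    "onset_s": _ticks_to_seconds(tick, tempo_changes, division),
                    "pitch": pitch,
                    "velocity": vel,
                }
            )
    return pd.DataFrame(rows).sort_values("onset_s", ignore_index=True)


def _parse_track(
    data: bytes, tempo_changes: list[tuple[int, int]]
) -> list[tuple[int, int, int]]:
    """Parse one MTrk payload; append tempo changes, return note-ons."""
    pos = 0
    tick = 0
    status = 0
    notes = []
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        byte = data[pos]
        if byte & 0x80:
            status = byte
            pos += 1
        if status == 0xFF:  # meta
            meta_type = data[pos]
            length, p2 = _read_varlen(data, pos + 1)
            payload = data[p2 : p2 + length]
            if meta_type == 0x51 and length == 3:
                tempo_changes.append((tick, int.from_bytes(payload, "big")))
            pos = p2 + length
            if meta_type == 0x2F:  # end of track
                break
        elif status in (0xF0, 0xF7):  # sysex
            length, p2 = _read_varlen(data, pos)
            pos = p2 + length
        else:
            kind = status & 0xF0
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            args = data[pos : pos + n_data]
            pos += n_data
            if kind == 0x90 and args[1] > 0:  # note-on with velocity
                notes.append((tick, args[0], args[1]))
    return notes


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _ticks_to_seconds(
    tick: int, tempo_changes: list[tuple[int, int]], division: int
) -> float:
    seconds = 0.0
    prev_tick, tempo = tempo_changes[0]
    for change_tick, new_tempo in tempo_changes[1:]:
        if change_tick >= tick:
            break
        seconds += (change_tick - prev_tick) * tempo / 1e6 / division
        prev_tick, tempo = change_tick, new_tempo
    seconds += (tick - prev_tick) * tempo / 1e6 / division
    return seconds


def annotate_sync_notes(
    onsets: pd.DataFrame,
    annotation: pd.DataFrame,
    track_roles: dict[int, str] | None = None,
) -> list[NoteEvent]:
    """Turn raw SMF note-ons into :class:`NoteEvent` sync points.

    ``annotation`` has columns ``part, note_ordinal, sync_index, chord_group``
    where ``note_ordinal`` is the 0-based index of the note within its part
    (time order).  ``track_roles`` maps SMF track number to "P"/"S"
    (default: first note-bearing track is P, second is S).
    """
    note_tracks = sorted(onsets["track"].unique())
    if track_roles is None:
        if len(note_tracks) != 2:
            raise ValueError("need exactly two note-bearing tracks or track_roles")
        track_roles = {note_tracks[0]: "P", note_tracks[1]: "S"}
    onsets = onsets.assign(part=onsets["track"].map(track_roles))
    events = []
    for row in annotation.itertuples(index=False):
        part_notes = onsets[onsets["part"] == row.part].sort_values("onset_s")
        if row.note_ordinal >= len(part_notes):
            raise ValueError(
                f"note_ordinal {row.note_ordinal} out of range for part {row.part}"
            )
        chord = getattr(row, "chord_group", None)
        if chord is not None and pd.isna(chord):
            chord = None
        events.append(
            NoteEvent(
                part=row.part,
                sync_index=int(row.sync_index),
                onset=float(part_notes["onset_s"].iloc[int(row.note_ordinal)]),
                chord_group=None if chord is None else int(chord),
            )
        )
    _validate_sync_points(events)
    events.sort(key=lambda e: (e.part, e.onset))
    return events


# ---------------------------------------------------------------------------
# Slider event logs
# ---------------------------------------------------------------------------


def read_slider_events(path: str | Path) -> list[SliderEventStream]:
    """Read sparse slider logs (columns ``participant, stimulus, modality, t,
    value`` plus optional ``load`` and ``presentation``).

    A trial id appearing under two ``load`` indices marks a trial that was
    loaded twice; the earlier, incomplete load is flagged ``partial``.  A
    ``presentation`` index >= 2 flags a repeated stimulus presentation.
    """
    df = pd.read_csv(path)
    required = {"participant", "stimulus", "modality", "t", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"slider CSV needs columns {sorted(required)}")
    if "load" not in df.columns:
        df["load"] = 0
    if "presentation" not in df.columns:
        df["presentation"] = 1
    streams = []
    keys = ["participant", "stimulus", "modality", "presentation"]
    for (pid, sid, mod, pres), trial in df.groupby(keys, sort=True):
        loads = sorted(trial["load"].unique())
        for load in loads:
            sub = trial[trial["load"] == load].sort_values("t")
            events = sub[["t", "value"]].to_numpy(float)
            events = events[~np.isnan(events[:, 0])]  # rows logging no event
            if load != loads[-1]:
                status = "partial"
            elif int(pres) > 1:
                status = "repeat"
            else:
                status = "complete"
            streams.append(
                SliderEventStream(str(pid), str(sid), str(mod), events, status)
            )
    return streams


def write_slider_events(path: str | Path, streams: Iterable[SliderEventStream]) -> None:
    rows = []
    for s in streams:
        pres = 2 if s.trial_status == "repeat" else 1
        if len(s.events) == 0:
            rows.append(
                {
                    "participant": s.participant_id,
                    "stimulus": s.stimulus_id,
                    "modality": s.modality,
                    "t": np.nan,
                    "value": np.nan,
                    "load": 0,
                    "presentation": pres,
                }
            )
        for t, v in s.events:
            rows.append(
                {
                    "participant": s.participant_id,
                    "stimulus": s.stimulus_id,
                    "modality": s.modality,
                    "t": t,
                    "value": v,
                    "load": 0,
                    "presentation": pres,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
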