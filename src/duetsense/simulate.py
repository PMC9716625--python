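"""Synthetic duo-performance studies with known ground truth.

The generator emulates the full study design — 2 stimulus groups (piano,
clarinet) x 8 performances x 3 presentation modalities (AO, VO, AV) x 30
participants (10 novices, 10 pianists, 10 clarinetists) — at configurable
scale:

* **Duo motion**: each paired body part carries a shared oscillation at the
  stimulus' base period (weight = the coupling ``kappa``), an idiosyncratic
  oscillation per musician, and smooth low-pass noise, at 240 Hz.  Head
  amplitude is largest by default, the chest smallest, so body-part QoM and
  cross-wavelet power orderings are controlled.
* **Note events**: Primo onsets on an expressive-timing grid; Secondo onsets
  are Primo plus Normal(0, sigma_async) noise.  Designated sync points are
  chords with 2-3 near-simultaneous notes per part.
* **Intensity**: a phrase-shaped dynamics curve with per-note attack
  transients, emitted at 10 Hz (and optionally rendered as a sine-tone WAV).
* **Ratings**: a latent togetherness process — baseline 50 plus group-specific
  weights on lagged, centred log-features plus AR(1) noise — emitted as
  sparse slider change events, exactly as the acquisition platform logs them.
* **Fixations**: AOI-labelled gaze samples from a sticky Markov chain with
  the Secondo upper body attracting the most dwell time.

Everything derives deterministically from ``SimulationConfig.seed``; the
ground-truth manifest written by :func:`generate_study` records every true
parameter so downstream recovery tests never peek at generator internals.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .audio import IntensityEnvelope, write_wav
from .io import (
    BODY_PARTS,
    DuoRecording,
    MarkerTrajectory,
    NoteEvent,
    SliderEventStream,
    write_marker_trajectories,
    write_note_events,
    write_slider_events,
)

__all__ = [
    "SimulationConfig",
    "simulate_duo_motion",
    "simulate_onsets",
    "simulate_intensity",
    "render_audio",
    "simulate_ratings",
    "simulate_fixations",
    "generate_study",
    "miniature_config",
]

_AXIS_WEIGHTS = np.array([1.0, 0.45, 0.2])


@dataclass
class SimulationConfig:
    """All true parameters of a synthetic study."""

    seed: int = 0
    n_novices: int = 10
    n_pianists: int = 10
    n_clarinetists: int = 10
    n_stimuli_per_group: int = 8
    n_repeats_per_group: int = 2  # stimuli presented twice per group
    duration: float = 47.0  # s
    rate: float = 240.0  # Hz, motion capture
    out_rate: float = 10.0  # Hz, feature / rating grid
    modalities: tuple[str, ...] = ("AO", "VO", "AV")
    # motion
    amplitude_mm: dict[str, float] = field(
        default_factory=lambda: {
            "head": 25.0,
            "r_arm": 18.0,
            "l_arm": 14.0,
            "r_shoulder": 12.0,
            "l_shoulder": 11.0,
            "chest": 6.0,
            "l_hand": 20.0,
            "r_hand": 20.0,
        }
    )
    coupling: dict[str, float] = field(
        default_factory=lambda: {
            "head": 0.70,
            "r_arm": 0.65,
            "l_arm": 0.50,
            "r_shoulder": 0.50,
            "l_shoulder": 0.50,
            "chest": 0.40,
            "l_hand": 0.30,
            "r_hand": 0.30,
        }
    )
    base_period_range: tuple[float, float] = (0.8, 2.5)  # s
    # per-stimulus jitter of each part's coupling and amplitude: performances
    # differ in which body parts carried the coordination, which keeps the
    # six pair-power predictors decorrelated across stimuli (low VIF)
    coupling_jitter: float = 0.2
    amplitude_jitter: float = 0.3
    motion_noise_mm: float = 0.5
    secondo_amplitude_scale: float = 0.9
    # note events
    n_sync: int = 16
    chord_sync_indices: tuple[int, ...] = (11, 12, 13, 14)
    sigma_async_ms: dict[str, float] = field(
        default_factory=lambda: {"piano": 159.0, "clarinet": 172.0}
    )
    # rating process
    true_lag: float = 1.0  # s; the lag the CV analysis should recover
    ar1_rho: float = 0.97  # smooth latent drift at the 100 ms step
    noise_sd: float = 5.0
    participant_sd: float = 5.0  # random-intercept SD (variance 25)
    # Emission deadband in rating units.  A small default keeps the densified
    # series faithful to the latent process (a wide deadband censors small
    # feature-driven changes and attenuates every fitted slope); a value of
    # ~4.0 instead reproduces the sparser ~1-change-per-1.1 s event density
    # real slider logs show, at the cost of that censoring.
    slider_threshold: float = 0.5
    group_betas: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "novice": {"intensity": 3.8, "cwt_r_arm": 0.7},
            "pianist": {"cwt_chest": 0.5},
            "clarinetist": {"cwt_chest": 0.5, "abs_asynchrony": -0.006},
        }
    )
    group_offsets: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "novice": {"AO": 8.0, "VO": 2.0, "AV": 8.0},
            "pianist": {"AO": 0.0, "VO": 0.0, "AV": 0.0},
            "clarinetist": {"AO": -3.0, "VO": -3.0, "AV": -3.0},
        }
    )

    def __post_init__(self) -> None:
        for part, k in self.coupling.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"coupling for {part} outside [0, 1]: {k}")
        if self.duration <= self.base_period_range[1]:
            raise ValueError("duration must exceed the largest base period")

    def stimulus_ids(self) -> list[str]:
        return [
            f"{grp}_{i + 1:02d}"
            for grp in ("piano", "clarinet")
            for i in range(self.n_stimuli_per_group)
        ]

    def participants(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_novices):
            rows.append(("nov%02d" % (i + 1), "novice", "none", "novice"))
        for i in range(self.n_pianists):
            rows.append(("pia%02d" % (i + 1), "semi-pro", "pianist", "pianist"))
        for i in range(self.n_clarinetists):
            rows.append(("cla%02d" % (i + 1), "semi-pro", "clarinetist",
                         "clarinetist"))
        return pd.DataFrame(
            rows, columns=["participant", "background", "instrument", "sim_group"]
        )

    def rng_for(self, *labels) -> np.random.Generator:
        """Deterministic child generator for one simulation component
        (process-independent: keyed by a CRC of the labels, not ``hash``)."""
        digest = zlib.crc32("|".join(map(str, labels)).encode())
        return np.random.default_rng([self.seed, digest])


def miniature_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A small study (2 participants/group, 2 stimuli/group, 20 s) that runs
    the full pipeline in well under two minutes."""
    defaults = dict(
        seed=seed,
        n_novices=2,
        n_pianists=2,
        n_clarinetists=2,
        n_stimuli_per_group=2,
        n_repeats_per_group=0,
        duration=20.0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


# ---------------------------------------------------------------------------
# Motion
# ---------------------------------------------------------------------------


def _smooth_noise(rng, n: int, rate: float, sd_mm: float) -> np.ndarray:
    """Low-pass-filtered Gaussian noise (3-vector), ~150 ms correlation, so
    Savitzky-Golay double differentiation does not let positional jitter
    dominate the oscillatory acceleration signal."""
    if sd_mm == 0:
        return np.zeros((n, 3))
    raw = rng.standard_normal((n, 3))
    smooth = gaussian_filter1d(raw, sigma=0.15 * rate, axis=0)
    std = smooth.std(axis=0)
    std[std == 0] = 1.0
    return smooth / std * sd_mm


def base_period_for(cfg: SimulationConfig, stimulus_id: str) -> float:
    """The stimulus' true common oscillation period (s)."""
    return float(
        cfg.rng_for("base-period", stimulus_id).uniform(*cfg.base_period_range)
    )


def simulate_duo_motion(
    cfg: SimulationConfig, stimulus_id: str
) -> DuoRecording:
    """One duo stimulus: coupled oscillatory marker motion at 240 Hz."""
    group = stimulus_id.split("_")[0]
    rng = cfg.rng_for("motion", stimulus_id)
    n = int(round(cfg.duration * cfg.rate))
    t = np.arange(n) / cfg.rate
    base_period = base_period_for(cfg, stimulus_id)
    trajectories: dict[str, MarkerTrajectory] = {}
    for part in BODY_PARTS:
        amp = cfg.amplitude_mm[part] * (
            1.0 + rng.uniform(-cfg.amplitude_jitter, cfg.amplitude_jitter)
        )
        kappa = float(
            np.clip(
                cfg.coupling[part]
                + rng.uniform(-cfg.coupling_jitter, cfg.coupling_jitter),
                0.0,
                1.0,
            )
        )
        phase = rng.uniform(0, 2 * np.pi)
        # slow common phase drift shared by both musicians (expressive timing)
        drift = gaussian_filter1d(rng.standard_normal(n), sigma=2.0 * cfg.rate)
        drift = drift / max(drift.std(), 1e-12) * 1.5
        shared = np.sin(2 * np.pi * t / base_period + phase + drift)
        for role, scale in (("P", 1.0), ("S", cfg.secondo_amplitude_scale)):
            # idiosyncratic sway tempi kept disjoint between the musicians so
            # uncoupled motion shares no stable common periodicity
            lo, hi = (0.50, 0.65) if role == "P" else (0.72, 0.87)
            idio_period = base_period * rng.uniform(lo, hi)
            idio_phase = rng.uniform(0, 2 * np.pi)
            idio = np.sin(2 * np.pi * t / idio_period + idio_phase)
            signal = amp * scale * (kappa * shared + (1.0 - kappa) * idio)
            rest = rng.uniform(-500, 500, size=3)
            xyz = (
                rest
                + signal[:, None] * _AXIS_WEIGHTS
                + _smooth_noise(rng, n, cfg.rate, cfg.motion_noise_mm)
            )
            mid = f"{role}_{part}"
            trajectories[mid] = MarkerTrajectory(mid, xyz, cfg.rate)
    if group == "clarinet":
        for role in ("P", "S"):
            for k in range(2):
                rest = rng.uniform(-500, 500, size=3)
                wob = np.sin(2 * np.pi * t / base_period + rng.uniform(0, 2 * np.pi))
                xyz = (
                    rest
                    + 6.0 * wob[:, None] * _AXIS_WEIGHTS
                    + _smooth_noise(rng, n, cfg.rate, cfg.motion_noise_mm)
                )
                mid = f"{role}_inst{k + 1}"
                trajectories[mid] = MarkerTrajectory(mid, xyz, cfg.rate)
    return DuoRecording(
        stimulus_id=stimulus_id,
        stimulus_group=group,
        trajectories=trajectories,
    )


# ---------------------------------------------------------------------------
# Note events
# ---------------------------------------------------------------------------


def simulate_onsets(
    cfg: SimulationConfig,
    stimulus_id: str,
    n_sync: int | None = None,
    chords: tuple[int, ...] | None = None,
) -> list[NoteEvent]:
    """Sync-point onsets: expressive Primo timing, Normal Secondo asynchrony."""
    group = stimulus_id.split("_")[0]
    n_sync = cfg.n_sync if n_sync is None else n_sync
    if n_sync < 1:
        raise ValueError("need at least one sync point")
    chords = cfg.chord_sync_indices if chords is None else chords
    rng = cfg.rng_for("onsets", stimulus_id)
    sigma_s = cfg.sigma_async_ms.get(group, 150.0) / 1000.0
    margin = min(2.0, 0.1 * cfg.duration)
    grid = np.linspace(margin, cfg.duration - margin, n_sync)
    spacing = grid[1] - grid[0] if n_sync > 1 else cfg.duration
    primo = np.sort(grid + rng.uniform(-0.1, 0.1, size=n_sync) * spacing)
    events: list[NoteEvent] = []
    for i, p_onset in enumerate(primo):
        sync_index = i + 1
        s_onset = max(0.0, p_onset + rng.normal(0.0, sigma_s))
        if sync_index in chords:
            for part, last in (("P", p_onset), ("S", s_onset)):
                n_members = int(rng.integers(2, 4))
                members = [last] + list(
                    last - rng.uniform(0.005, 0.04, size=n_members - 1)
                )
                for onset in members:
                    events.append(
                        NoteEvent(part, sync_index, max(0.0, onset), sync_index)
                    )
        else:
            events.append(NoteEvent("P", sync_index, p_onset))
            events.append(NoteEvent("S", sync_index, s_onset))
    events.sort(key=lambda e: (e.part, e.onset))
    return events


# ---------------------------------------------------------------------------
# Intensity / audio
# ---------------------------------------------------------------------------


def simulate_intensity(
    cfg: SimulationConfig,
    events: list[NoteEvent],
    stimulus_id: str,
    dynamics: str = "phrases",
) -> IntensityEnvelope:
    """Phrase-shaped dynamics curve with per-note attack transients, 10 Hz."""
    rng = cfg.rng_for("intensity", stimulus_id)
    n = int(round(cfg.duration * cfg.out_rate)) - 1  # match RMS frame count
    t = np.arange(n) / cfg.out_rate
    if dynamics == "flat":
        env = np.full(n, 0.5)
    elif dynamics == "crescendo":
        env = np.linspace(0.3, 0.6, n)
    else:
        # three phrase arcs spanning ~13/15/18 shares of the duration
        bounds = np.array([0.0, 13.0, 28.0, 46.0]) / 46.0 * cfg.duration
        env = np.full(n, 0.05)
        for k, peak in enumerate((0.8, 1.0, 0.9)):
            lo, hi = bounds[k], bounds[k + 1]
            inside = (t >= lo) & (t < hi)
            x = (t[inside] - lo) / (hi - lo)
            env[inside] += peak * 0.5 * (1 - np.cos(2 * np.pi * x)) * 0.5
    for e in events:
        if e.part != "P":
            continue
        attack = 0.15 * np.exp(-(t - e.onset) / 0.25)
        attack[t < e.onset] = 0.0
        env = env + attack
    env = env * rng.uniform(0.9, 1.1)
    return IntensityEnvelope(np.maximum(env, 1e-4), cfg.out_rate, 0.2, 0.1)


def render_audio(
    envelope: IntensityEnvelope, duration: float, rate: int = 22050
) -> np.ndarray:
    """Render the intensity curve as an amplitude-modulated sine tone whose
    windowed RMS recovers the programmed envelope."""
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    env_t = envelope.times + envelope.window / 2.0
    amp = np.interp(t, env_t, envelope.values) * np.sqrt(2.0)
    return amp * np.sin(2 * np.pi * 440.0 * t)


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

_MODALITY_FEATURES = {
    "AO": ("intensity", "abs_asynchrony"),
    "VO": ("qom_total", "cwt_head", "cwt_chest", "cwt_l_shoulder",
           "cwt_r_shoulder", "cwt_l_arm", "cwt_r_arm"),
    "AV": ("intensity", "abs_asynchrony", "qom_total", "cwt_head", "cwt_chest",
           "cwt_l_shoulder", "cwt_r_shoulder", "cwt_l_arm", "cwt_r_arm"),
}


def simulate_ratings(
    cfg: SimulationConfig,
    features: pd.DataFrame,
    sim_group: str,
    participant: str,
    stimulus_id: str,
    modality: str,
    participant_offset: float = 0.0,
) -> SliderEventStream:
    """Sparse slider events from the latent togetherness process.

    Latent rating: ``50 + group/modality offset + participant intercept +
    sum_j beta_j * (logfeature_j(t - L) - mean)`` plus AR(1) noise, clipped to
    the slider scale; an event is emitted at every 100 ms step at which the
    latent value moved at least ``slider_threshold`` away from the last
    emitted value.  ``features`` holds the *log-transformed, centred* feature
    columns at 10 Hz for this stimulus (see
    :func:`duetsense.pipeline.prepare_truth_features`).
    """
    rng = cfg.rng_for("ratings", participant, stimulus_id, modality)
    betas = cfg.group_betas.get(sim_group, {})
    offset = cfg.group_offsets.get(sim_group, {}).get(modality, 0.0)
    visible = _MODALITY_FEATURES[modality]
    n = len(features)
    shift = int(round(cfg.true_lag * cfg.out_rate))
    latent = np.full(n, 50.0 + offset + participant_offset)
    for name, beta in betas.items():
        if name not in visible or name not in features.columns:
            continue
        x = features[name].to_numpy(float)
        lagged = np.empty(n)
        lagged[shift:] = x[: n - shift]
        lagged[:shift] = x[0]
        latent = latent + beta * lagged
    # AR(1) noise at the 10 Hz step with marginal SD noise_sd
    rho, sd = cfg.ar1_rho, cfg.noise_sd
    if sd > 0:
        eps = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, sd)
        for i in range(1, n):
            noise[i] = rho * noise[i - 1] + eps[i]
        latent = latent + noise
    latent = np.clip(latent, 0.0, 100.0)
    events = []
    last = 50.0
    for i in range(1, n):
        if abs(latent[i] - last) >= cfg.slider_threshold:
            last = latent[i]
            events.append((i / cfg.out_rate, last))
    return SliderEventStream(
        participant, stimulus_id, modality, np.array(events).reshape(-1, 2)
    )


# ---------------------------------------------------------------------------
# Fixations
# ---------------------------------------------------------------------------

_AOI_PROBS = {
    "S_UpperBody": 0.32,
    "P_UpperBody": 0.26,
    "Center": 0.17,
    "S_Head": 0.10,
    "P_Head": 0.09,
    "none": 0.06,
}


def simulate_fixations(
    cfg: SimulationConfig,
    participant: str,
    stimulus_id: str,
    sample_rate: float = 60.0,
    mean_dwell: float = 0.5,
) -> pd.DataFrame:
    """AOI-labelled gaze samples from a sticky Markov chain (mean dwell
    ~``mean_dwell`` seconds; Secondo upper body attracts the most time)."""
    rng = cfg.rng_for("fixations", participant, stimulus_id)
    n = int(round(cfg.duration * sample_rate))
    labels = list(_AOI_PROBS)
    probs = np.array(list(_AOI_PROBS.values()))
    probs = probs / probs.sum()
    switch_p = 1.0 / (mean_dwell * sample_rate)
    states = np.empty(n, dtype=object)
    current = labels[rng.choice(len(labels), p=probs)]
    for i in range(n):
        if rng.random() < switch_p:
            current = labels[rng.choice(len(labels), p=probs)]
        states[i] = current
    return pd.DataFrame(
        {
            "participant": participant,
            "stimulus": stimulus_id,
            "t": np.arange(n) / sample_rate,
            "aoi": states,
        }
    )


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


def generate_study(
    cfg: SimulationConfig,
    outdir: str | Path,
    force: bool = False,
    write_audio: bool = False,
    write_fixation_samples: bool = True,
) -> Path:
    """Write a full on-disk study bundle consumable by the whole pipeline.

    Layout::

        outdir/
          manifest.json              all true parameters + seed
          metadata/participants.csv
          stimuli/<id>/markers.csv, events.csv, intensity.csv [, audio.wav]
          ratings/slider_events.csv
          fixations/fixations.csv
    """
    from . import pipeline  # deferred: pipeline imports the analysis modules

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} exists; pass force=True to overwrite")
    (outdir / "metadata").mkdir(parents=True, exist_ok=True)
    (outdir / "ratings").mkdir(exist_ok=True)
    (outdir / "fixations").mkdir(exist_ok=True)

    participants = cfg.participants()
    participants.to_csv(outdir / "metadata" / "participants.csv", index=False)

    truth_features: dict[str, pd.DataFrame] = {}
    base_periods: dict[str, float] = {}
    for sid in cfg.stimulus_ids():
        stim_dir = outdir / "stimuli" / sid
        stim_dir.mkdir(parents=True, exist_ok=True)
        rec = simulate_duo_motion(cfg, sid)
        events = simulate_onsets(cfg, sid)
        env = simulate_intensity(cfg, events, sid)
        write_marker_trajectories(stim_dir / "markers.csv", rec.trajectories)
        write_note_events(stim_dir / "events.csv", events)
        pd.DataFrame({"t": env.times, "value": env.values}).to_csv(
            stim_dir / "intensity.csv", index=False
        )
        if write_audio:
            write_wav(
                stim_dir / "audio.wav",
                render_audio(env, cfg.duration),
                22050,
            )
        rec.note_events = events
        rec.intensity = env
        truth_features[sid] = pipeline.prepare_truth_features(cfg, rec, env, events)
        base_periods[sid] = base_period_for(cfg, sid)
    truth_features = pipeline.finalize_truth_features(truth_features)

    intercept_rng = cfg.rng_for("participant-intercepts")
    offsets = {
        row.participant: float(intercept_rng.normal(0.0, cfg.participant_sd))
        for row in participants.itertuples()
    }
    streams: list[SliderEventStream] = []
    for row in participants.itertuples():
        for sid in cfg.stimulus_ids():
            for modality in cfg.modalities:
                streams.append(
                    simulate_ratings(
                        cfg,
                        truth_features[sid],
                        row.sim_group,
                        row.participant,
                        sid,
                        modality,
                        offsets[row.participant],
                    )
                )
    # repeated presentations of the first n stimuli per group
    repeated = [
        f"{grp}_{i + 1:02d}"
        for grp in ("piano", "clarinet")
        for i in range(cfg.n_repeats_per_group)
    ]
    for row in participants.itertuples():
        for sid in repeated:
            modality = cfg.modalities[0]
            s = simulate_ratings(
                cfg,
                truth_features[sid],
                row.sim_group,
                row.participant,
                sid,
                modality,
                offsets[row.participant],
            )
            s.trial_status = "repeat"
            streams.append(s)
    write_slider_events(outdir / "ratings" / "slider_events.csv", streams)

    if write_fixation_samples:
        frames = [
            simulate_fixations(cfg, row.participant, sid)
            for row in participants.itertuples()
            for sid in cfg.stimulus_ids()
        ]
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "fixations" / "fixations.csv", index=False
        )

    manifest = {
        "config": _config_dict(cfg),
        "base_periods": base_periods,
        "participant_offsets": offsets,
        "repeated_stimuli": repeated,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


def _config_dict(cfg: SimulationConfig) -> dict:
    out = dataclasses.asdict(cfg)
    for key, val in out.items():
        if isinstance(val, tuple):
            out[key] = list(val)
    return out
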