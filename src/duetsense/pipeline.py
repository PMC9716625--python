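"""End-to-end analysis: features -> model tables -> lag CV -> model battery.

The driver mirrors the study's analysis sequence: extract stimulus features
(total QoM, six body-part cross-wavelet power series, RMS intensity) on the
10 Hz rating grid; densify and screen the slider logs; align ratings with
features at candidate perceptual lags of 1, 2 and 3 s; select the lag by
participant-folded 10-fold cross-validation; then fit the modality x
expertise togetherness battery, the synchronization models at per-sync-point
references, the factorial ANOVAs on per-trial means, and the body-part
comparison models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats
from .audio import (
    IntensityEnvelope,
    note_asynchronies,
    rms_envelope,
    summarize_asynchrony,
)
from .coordination import PeriodGrid, coordination_all_pairs
from .io import (
    COORDINATION_PARTS,
    DuoRecording,
    NoteEvent,
    SliderEventStream,
    read_marker_trajectories,
    read_note_events,
    read_slider_events,
)
from .kinematics import quantity_of_motion
from .ratings import (
    RatingSeries,
    densify,
    exclude_trials,
    lag_align,
    log_transform,
    sync_reference_ratings,
)

logger = logging.getLogger("duetsense")

__all__ = [
    "FEATURE_COLUMNS",
    "extract_stimulus_features",
    "build_model_tables",
    "build_sync_table",
    "prepare_truth_features",
    "finalize_truth_features",
    "load_study",
    "analyze_study",
    "StudyData",
    "StudyAnalysis",
]

FEATURE_COLUMNS = ["intensity", "qom_total"] + [
    f"cwt_{p}" for p in COORDINATION_PARTS
]

LOG_COLUMNS = FEATURE_COLUMNS  # all skewed, all log-transformed for modelling


def default_grid(duration: float) -> PeriodGrid:
    """Period grid 0.3-7 s, capped so the largest wavelet fits the series."""
    return PeriodGrid.from_range(0.3, min(7.0, duration / 2.2))


def extract_stimulus_features(
    rec: DuoRecording,
    intensity: IntensityEnvelope | None = None,
    audio: tuple[np.ndarray, int] | None = None,
    grid: PeriodGrid | None = None,
    out_rate: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Raw (un-logged) 10 Hz feature table of one stimulus.

    Columns: ``t, intensity, qom_total, cwt_<part>`` for the six paired body
    parts; also returns the dominant cross-wavelet period per pair.  Sound
    intensity comes from ``intensity`` (a precomputed envelope) or is
    computed from ``audio``; if neither is given the column is NaN (a
    video-only stimulus).
    """
    if grid is None:
        grid = default_grid(rec.duration)
    qom = quantity_of_motion(rec, scope="total", out_rate=out_rate)
    coord = coordination_all_pairs(rec, out_rate=out_rate, grid=grid)
    if intensity is None and audio is not None:
        intensity = rms_envelope(audio[0], audio[1], out_rate)
    lengths = [qom.n_samples] + [c.power.n_samples for c in coord.values()]
    if intensity is not None:
        lengths.append(len(intensity.values))
    n = min(lengths)
    data = {"t": np.arange(n) / out_rate, "qom_total": qom.values[:n]}
    data["intensity"] = (
        intensity.values[:n] if intensity is not None else np.full(n, np.nan)
    )
    for part, series in coord.items():
        data[f"cwt_{part}"] = series.power.values[:n]
    periods = {part: series.dominant_period for part, series in coord.items()}
    return pd.DataFrame(data)[["t"] + FEATURE_COLUMNS], periods


def build_model_tables(
    features: dict[str, pd.DataFrame],
    series: list[RatingSeries],
    participants: pd.DataFrame,
    stimulus_groups: dict[str, str],
    lags: tuple[float, ...] = (1.0, 2.0, 3.0),
) -> tuple[dict[float, pd.DataFrame], dict[str, float]]:
    """Lag-aligned model tables with log-transformed predictors.

    One log offset per predictor, computed from the features pooled across
    stimuli so the transform is identical in every trial; the offsets are
    returned for the run manifest.  Each output row pairs a trial's response
    at ``t + lag`` with the stimulus features at ``t``.
    """
    pooled = pd.concat(features.values(), ignore_index=True)
    _, eps = log_transform(pooled, LOG_COLUMNS)
    log_features = {
        sid: log_transform(df, LOG_COLUMNS, eps)[0] for sid, df in features.items()
    }
    meta = participants.set_index("participant")
    tables: dict[float, pd.DataFrame] = {}
    for lag in lags:
        rows = []
        for s in series:
            aligned = lag_align(s, log_features[s.stimulus_id], lag)
            aligned["background"] = meta.loc[s.participant_id, "background"]
            aligned["instrument"] = meta.loc[s.participant_id, "instrument"]
            aligned["stimulus_group"] = stimulus_groups[s.stimulus_id]
            rows.append(aligned)
        tables[lag] = pd.concat(rows, ignore_index=True)
    return tables, eps


def build_sync_table(
    series: list[RatingSeries],
    events: dict[str, list[NoteEvent]],
    participants: pd.DataFrame,
    lag: float,
) -> pd.DataFrame:
    """Per-sync-point responses joined with asynchronies (AO and AV trials)."""
    meta = participants.set_index("participant")
    async_by_stim = {
        sid: pd.DataFrame(
            {
                "sync_index": [r.sync_index for r in note_asynchronies(evs)],
                "asynchrony": [r.asynchrony for r in note_asynchronies(evs)],
                "abs_asynchrony": [
                    r.abs_asynchrony for r in note_asynchronies(evs)
                ],
            }
        )
        for sid, evs in events.items()
    }
    frames = []
    for s in series:
        if s.modality not in ("AO", "AV"):
            continue
        refs, _dropped = sync_reference_ratings(s, events[s.stimulus_id], lag)
        if refs.empty:
            continue
        merged = refs.merge(async_by_stim[s.stimulus_id], on="sync_index")
        merged["background"] = meta.loc[s.participant_id, "background"]
        merged["instrument"] = meta.loc[s.participant_id, "instrument"]
        frames.append(merged)
    return pd.concat(frames, ignore_index=True)


def prepare_truth_features(cfg, rec, env, events) -> pd.DataFrame:
    """Raw feature table of one synthetic stimulus plus the per-sync-point
    |asynchrony| step series (ms); input to :func:`finalize_truth_features`.
    """
    feats, _ = extract_stimulus_features(
        rec, intensity=env, grid=default_grid(cfg.duration), out_rate=cfg.out_rate
    )
    records = note_asynchronies(events)
    refs: dict[int, float] = {}
    for e in events:
        refs[e.sync_index] = max(refs.get(e.sync_index, -np.inf), e.onset)
    t = feats["t"].to_numpy()
    step = np.zeros(len(t))
    abs_by_idx = {r.sync_index: r.abs_asynchrony for r in records}
    out_rate = cfg.out_rate
    for sync_index in sorted(refs, key=refs.get):
        # switch at the grid sample nearest the reference, the same sample
        # the per-sync-point extraction reads at reference + lag
        ref_grid = np.round(refs[sync_index] * out_rate) / out_rate
        step[t >= ref_grid - 1e-9] = abs_by_idx[sync_index]
    feats = feats.copy()
    feats["abs_asynchrony"] = step
    return feats


def finalize_truth_features(
    raw: dict[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Pooled log transform and pooled centring of the generator's features.

    The rating generator defines latent togetherness on the same log scale
    the models fit, with one offset and one centring constant per feature
    *pooled across stimuli* — exactly mirroring how the model tables are
    built — so fitted coefficients are directly comparable with the
    generating weights on both the within- and between-stimulus axes.
    """
    pooled = pd.concat(raw.values(), ignore_index=True)
    _, eps = log_transform(pooled, LOG_COLUMNS)
    logged = {sid: log_transform(df, LOG_COLUMNS, eps)[0]
              for sid, df in raw.items()}
    pooled_log = pd.concat(logged.values(), ignore_index=True)
    centers = {col: float(pooled_log[col].mean()) for col in LOG_COLUMNS}
    centers["abs_asynchrony"] = float(pooled_log["abs_asynchrony"].mean())
    out = {}
    for sid, df in logged.items():
        df = df.copy()
        for col, c in centers.items():
            df[col] = df[col] - c
        out[sid] = df
    return out


# ---------------------------------------------------------------------------
# Study loading and end-to-end analysis
# ---------------------------------------------------------------------------


@dataclass
class StudyData:
    """An in-memory study bundle."""

    participants: pd.DataFrame
    recordings: dict[str, DuoRecording]
    events: dict[str, list[NoteEvent]]
    intensity: dict[str, IntensityEnvelope]
    streams: list[SliderEventStream]
    fixations: pd.DataFrame | None = None

    @property
    def stimulus_groups(self) -> dict[str, str]:
        return {sid: rec.stimulus_group for sid, rec in self.recordings.items()}


def load_study(study_dir: str | Path, rate: float = 240.0) -> StudyData:
    """Read a study bundle directory written by ``generate_study`` (or laid
    out the same way from real exports)."""
    study_dir = Path(study_dir)
    participants = pd.read_csv(study_dir / "metadata" / "participants.csv")
    recordings, events, intensity = {}, {}, {}
    for stim_dir in sorted((study_dir / "stimuli").iterdir()):
        sid = stim_dir.name
        markers = read_marker_trajectories(stim_dir / "markers.csv", rate)
        group = sid.split("_")[0]
        recordings[sid] = DuoRecording(sid, group, markers)
        events[sid] = read_note_events(stim_dir / "events.csv")
        env = pd.read_csv(stim_dir / "intensity.csv")
        intensity[sid] = IntensityEnvelope(
            env["value"].to_numpy(float), 10.0, 0.2, 0.1
        )
    streams = read_slider_events(study_dir / "ratings" / "slider_events.csv")
    fix_path = study_dir / "fixations" / "fixations.csv"
    fixations = pd.read_csv(fix_path) if fix_path.exists() else None
    return StudyData(participants, recordings, events, intensity, streams, fixations)


@dataclass
class StudyAnalysis:
    """Everything the end-to-end analysis computes."""

    features: dict[str, pd.DataFrame]
    dominant_periods: dict[str, dict[str, float]]
    exclusion_report: dict[str, int]
    log_offsets: dict[str, float]
    cv_by_modality: dict[str, stats.CvResult]
    selected_lag: float
    battery_fits: dict[str, stats.LmmFit]
    battery_table: pd.DataFrame
    sync_fits: dict[str, stats.LmmFit]
    sync_table: pd.DataFrame
    anova_background: stats.AnovaResult
    anova_instrument: stats.AnovaResult
    body_part_qom: pd.DataFrame
    body_part_cwt: pd.DataFrame
    asynchrony_summary: dict[str, tuple[float, float]]
    vif_av: pd.Series
    seed: int
    k_folds: int
    mean_ratings: pd.DataFrame = field(default=None, repr=False)

    def write_outputs(self, outdir: str | Path) -> None:
        """Tidy CSV outputs plus a JSON run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tidy = []
        for sid, df in self.features.items():
            melted = df.melt("t", var_name="feature", value_name="value")
            melted.insert(0, "stimulus", sid)
            tidy.append(melted)
        pd.concat(tidy, ignore_index=True).to_csv(
            outdir / "features.csv", index=False
        )
        cv = pd.concat(
            [r.table.assign(modality=m) for m, r in self.cv_by_modality.items()],
            ignore_index=True,
        )
        cv.to_csv(outdir / "lag_cv.csv", index=False)
        self.battery_table.to_csv(outdir / "togetherness_models.csv", index=False)
        self.sync_table.to_csv(outdir / "sync_models.csv", index=False)
        self.anova_background.anova_table.to_csv(outdir / "anova_background.csv")
        self.anova_instrument.anova_table.to_csv(outdir / "anova_instrument.csv")
        self.body_part_qom.to_csv(outdir / "body_part_qom.csv", index=False)
        self.body_part_cwt.to_csv(outdir / "body_part_cwt.csv", index=False)
        manifest = {
            "seed": self.seed,
            "k_folds": self.k_folds,
            "selected_lag_s": self.selected_lag,
            "alpha_battery": stats.ALPHA_BATTERY,
            "log_offsets": self.log_offsets,
            "exclusions": self.exclusion_report,
            "asynchrony_summary_ms": {
                g: {"mean_abs": m, "sd": s}
                for g, (m, s) in self.asynchrony_summary.items()
            },
            "vif_av": {k: float(v) for k, v in self.vif_av.items()},
            "dominant_periods_s": self.dominant_periods,
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )


def _mean_ratings_table(
    series: list[RatingSeries], participants: pd.DataFrame,
    stimulus_groups: dict[str, str],
) -> pd.DataFrame:
    meta = participants.set_index("participant")
    rows = []
    for s in series:
        rows.append(
            {
                "participant": s.participant_id,
                "stimulus": s.stimulus_id,
                "stimulus_group": stimulus_groups[s.stimulus_id],
                "modality": s.modality,
                "background": meta.loc[s.participant_id, "background"],
                "instrument": meta.loc[s.participant_id, "instrument"],
                "mean_rating": float(np.mean(s.values)),
            }
        )
    return pd.DataFrame(rows)


def _body_part_long(
    data: StudyData, which: str, out_rate: float = 10.0
) -> pd.DataFrame:
    """Long table (stimulus, t, body_part, value) of local QoM or CWT power."""
    rows = []
    for sid, rec in data.recordings.items():
        grid = default_grid(rec.duration)
        if which == "cwt":
            coord = coordination_all_pairs(rec, out_rate=out_rate, grid=grid)
        for part in COORDINATION_PARTS:
            if which == "qom":
                series = quantity_of_motion(
                    rec, scope="local", markers=[part], out_rate=out_rate
                ).values
            else:
                series = coord[part].power.values
            rows.append(
                pd.DataFrame(
                    {
                        "stimulus": sid,
                        "body_part": part,
                        "t": np.arange(len(series)) / out_rate,
                        "value": series,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def analyze_study(
    data: StudyData | str | Path,
    k: int = 10,
    seed: int = 0,
    lags: tuple[float, ...] = (1.0, 2.0, 3.0),
    body_parts: bool = True,
) -> StudyAnalysis:
    """Run the complete analysis pipeline on a study bundle."""
    if not isinstance(data, StudyData):
        data = load_study(data)
    logger.info("extracting features for %d stimuli", len(data.recordings))
    features, periods = {}, {}
    for sid, rec in data.recordings.items():
        features[sid], periods[sid] = extract_stimulus_features(
            rec, intensity=data.intensity.get(sid)
        )
    kept, report = exclude_trials(data.streams)
    logger.info("trials: %s", report)
    durations = {sid: rec.duration for sid, rec in data.recordings.items()}
    series = [densify(s, durations[s.stimulus_id]) for s in kept]
    tables, eps = build_model_tables(
        features, series, data.participants, data.stimulus_groups, lags
    )
    n_participants = data.participants["participant"].nunique()
    k_eff = min(k, n_participants)
    cv_by_modality: dict[str, stats.CvResult] = {}
    for model_n, (modality, predictors) in stats.MODEL_BATTERY.items():
        sub = {
            lag: tbl[tbl["modality"] == modality].reset_index(drop=True)
            for lag, tbl in tables.items()
        }
        cv_by_modality[modality] = stats.lag_crossvalidation(
            sub, predictors, k=k_eff, seed=seed
        )
        logger.info(
            "lag CV %s: selected %.0f s", modality,
            cv_by_modality[modality].selected_lag,
        )
    # one lag for the whole analysis: minimise the summed MAE across
    # modalities (RMSE, then the shorter lag, break ties)
    combined = (
        pd.concat([r.table for r in cv_by_modality.values()])
        .groupby("lag", as_index=False)[["mae", "rmse"]]
        .sum()
        .sort_values(["mae", "rmse", "lag"])
    )
    selected_lag = float(combined.iloc[0]["lag"])
    logger.info("selected lag: %.0f s", selected_lag)

    battery_fits, battery_table = stats.run_togetherness_models(
        tables[selected_lag]
    )
    sync_points = build_sync_table(
        series, data.events, data.participants, selected_lag
    )
    sync_fits, sync_table = stats.run_sync_models(sync_points)

    means = _mean_ratings_table(series, data.participants, data.stimulus_groups)
    anova_background = stats.anova_mean_ratings(
        means,
        factors=("background", "modality", "stimulus_group"),
        tukey_factors=(("background", "modality"),),
    )
    semi = means[means["background"] == "semi-pro"]
    anova_instrument = stats.anova_mean_ratings(
        semi,
        factors=("instrument", "modality", "stimulus_group"),
        tukey_factors=("instrument",),
    )

    if body_parts:
        _, body_part_qom = stats.compare_body_parts(_body_part_long(data, "qom"))
        _, body_part_cwt = stats.compare_body_parts(_body_part_long(data, "cwt"))
    else:
        body_part_qom = body_part_cwt = pd.DataFrame()

    async_summary = {}
    for group in ("piano", "clarinet"):
        records = []
        for sid, evs in data.events.items():
            if data.stimulus_groups[sid] == group:
                records.extend(note_asynchronies(evs))
        if records:
            async_summary[group] = summarize_asynchrony(records)

    av_table = tables[selected_lag]
    av_table = av_table[av_table["modality"] == "AV"]
    vif_av = stats.compute_vif(av_table, stats.MODEL_BATTERY["3"][1])

    return StudyAnalysis(
        features=features,
        dominant_periods=periods,
        exclusion_report=report,
        log_offsets=eps,
        cv_by_modality=cv_by_modality,
        selected_lag=selected_lag,
        battery_fits=battery_fits,
        battery_table=battery_table,
        sync_fits=sync_fits,
        sync_table=sync_table,
        anova_background=anova_background,
        anova_instrument=anova_instrument,
        body_part_qom=body_part_qom,
        body_part_cwt=body_part_cwt,
        asynchrony_summary=async_summary,
        vif_av=vif_av,
        seed=seed,
        k_folds=k_eff,
        mean_ratings=means,
    )
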