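# Methods

`duetsense` quantifies the audio and visual coordination cues of duo music
performances and models how continuously rated "togetherness" — an
audience's moment-to-moment sense that the two musicians are musically and
cognitively aligned — depends on those cues, the presentation modality
(audio-only AO, video-only VO, audio-plus-video AV) and the rater's musical
expertise. This note describes the models, the defaults and why they are
what they are, what the synthetic-data generator does and does not emulate,
and the numerical choices that matter.

## Kinematic features

Marker trajectories (mm, uniformly sampled, 240 Hz by convention) are
smoothed and differentiated with a Savitzky–Golay filter, window 25 frames
(~104 ms at 240 Hz), polynomial order 2. Order 2 is the lowest order that
leaves local extrema of sway-like motion intact while still suppressing
marker jitter; the derivative is exact for locally quadratic paths and
attenuates a 1 Hz sinusoid by about 1%.

*Quantity of motion* (QoM) is the per-sample Euclidean norm of each
marker's 3-D velocity (mm/s), summed over markers within a musician and
averaged across the two musicians ("total" scope; clarinet recordings
include the instrument markers, piano recordings do not because the
keyboards are stationary). "Local" QoM is the duo mean of a single paired
marker's speed. Feature series are brought to the 10 Hz rating grid by
averaging consecutive 100 ms blocks — the block mean conserves the series
mean exactly and is more noise-robust than decimation. The per-recording
grand mean (mean over non-overlapping 1 s bins of total QoM) characterises
a stimulus' overall movement energy.

QoM is invariant under rigid translation and axis permutation of all
markers and scales linearly with uniform velocity scaling; these invariances
are enforced by property tests.

## Cross-wavelet coordination

Between-musician coordination of a paired body part (chest, head, left and
right shoulder and arm; hands are excluded because hand motion is dictated
by sound production) is measured on the *acceleration* of the pair: the
Euclidean norm of the Savitzky–Golay second derivative per musician. Each
norm series is transformed with the continuous Morlet wavelet
(centre frequency ω₀ = 6, the standard admissible choice) on a period grid
of 1/20-octave steps spanning 0.3–7 s — the range from note-level to
semi-phrase-level periodicities. The transform is computed in the Fourier
domain with zero padding to the next power of two (Torrence–Compo
normalisation); an FFT-free direct-convolution implementation serves as the
test oracle (agreement < 1e-6 relative).

The cross matrix is the element-wise product `W_a · conj(W_b)`. Its raw
modulus equals `|W_a||W_b|` and is therefore blind to whether the two
musicians' oscillations are actually phase-locked. To make the measure
reward genuinely *common* oscillation, the complex cross matrix is smoothed
along time with a Gaussian of σ = 3 wavelet periods before the modulus is
taken (coherent averaging over roughly three wavelet envelopes; no
coherence normalisation or significance testing is applied). Stable
relative phase survives the averaging; drifting relative phase cancels.
With this default, a duo sharing a phase-drifting common oscillation shows
2–3× the median power of a time-reversed surrogate, and mean power responds
monotonically to the generator's coupling parameter. The smoothing width is
a parameter; `smooth_sigma_periods=None` gives the raw cross modulus.

The *dominant period* of a pair is the grid period with the highest
time-averaged (smoothed) cross power, chosen per stimulus per pair; exact
ties break toward the shorter period. The power row at the dominant period,
block-averaged to 10 Hz, is the pair's coordination series. The
cone-of-influence is not masked by default (series are long relative to the
analysed periods; edge effects are shared by all stimuli equally).

## Audio features

*Sound intensity* is the RMS amplitude in rectangular 0.2 s windows hopped
by 0.1 s — a 10 Hz series with 50% overlap. *Perceptual onsets* are
estimated from consecutive 10 ms windows within a coarse region containing
one attack: the onset is the start time of the first window whose RMS
reaches 70% of the regional maximum (≥, window start rather than centre, so
the estimate is biased consistently early; a region containing two attacks
separated by a deep dip raises an error unless the caller opts into taking
the earliest).

*Asynchronies* are defined per score-notated synchronization point as
`(onset_Secondo − onset_Primo) × 1000` ms, so **positive asynchrony means
the Primo sounded first (was leading)**. For chords, the latest onset
within the chord represents each musician before subtracting. Asynchronies
are invariant to shifting both parts by a constant and negate under part
swap. Summaries (mean and SD of |asynchrony|) pool sync points across the
recordings of a stimulus group; the SD is the population SD by default
(configurable via `ddof`).

## Ratings

Slider logs are sparse change events on a 0–100 scale whose handle starts
at the centre (50). Densification is previous-value (constant)
interpolation onto the grid t = 0.0, 0.1, … s; an event at exactly a grid
time takes effect at that sample. Trials flagged as partial (a trial loaded
twice, the first load incomplete) and second presentations of repeated
stimuli are excluded before modelling; trials in which the participant
never moved the slider are retained as flat series at the centre.

Because intensity, QoM and cross-wavelet power are strongly right-skewed,
predictors enter every model as `log(x + ε)` with one offset per predictor,
ε = (smallest positive pooled value) × 1e-3, pooled across stimuli so the
transform is identical in every trial; the offsets are recorded in the run
manifest. Lag alignment pairs the response at `t + lag` with predictors at
`t` and drops the trailing `lag` seconds; sub-150 ms mismatches between
stimulus and response durations are absorbed by truncating to the shorter.

## Mixed models with AR(1) residuals

The modelling core is the Gaussian linear mixed model

    y = X β + Z u + e,   u ~ N(0, τ² I),   e ~ N(0, σ² R(ρ)),

with a random intercept per participant (or per stimulus in the body-part
models) and first-order autoregressive correlation `R(ρ)` between
consecutive 100 ms samples within each within-stimulus rating series.
Estimation is maximum likelihood (REML by flag): each series is whitened by
the exact AR(1) square-root transform, after which the covariance is
`σ²(I + γ ZZᵀ)` with `γ = τ²/σ²`; β and σ² then have closed-form profiles
via the Woodbury identity (participant blocks are orthogonal, so all
determinants and quadratic forms reduce to per-group scalars), and the
remaining two-dimensional problem over `(atanh ρ, log γ)` is solved by
Nelder–Mead. The implementation agrees with R's `nlme::lme` with a `corAR1`
correlation structure to ~6 digits in β, ρ, τ², σ² and the log-likelihood
on test data, and reduces exactly to OLS when both variance components are
switched off.

Inference is Wald: t statistics on residual degrees of freedom
(n_obs − n_fixed). With tens of thousands of 100 ms samples per model the
df choice is immaterial; it is stated here because small-data users should
not over-read the p-values. A rank-deficient design raises immediately
("singular design"); boundary variance estimates and non-convergence are
flagged on the returned fit, never silently dropped.

Out-of-sample prediction uses the fixed effects only — random intercepts of
unseen participants are set to their zero mean — which is the natural rule
for scoring held-out participants.

## Lag selection

Candidate perceptual lags are 1, 2 and 3 s. For each lag and modality the
corresponding model (AO: intensity; VO: total QoM + six pair powers; AV:
both) is cross-validated with K = 10 folds *of participants* (ratings are
nested within participants, so row-wise folding would leak). Fold-wise MAE
and RMSE on held-out participants are averaged; the lag with the lowest MAE
wins, RMSE and then the shorter lag breaking ties (MAE is the primary
criterion because a deterministic rule is needed when the two disagree by
rounding). One lag is then used for the whole analysis: the lag minimising
the MAE summed over the three modalities (same tie rules). Fold assignment
is a seeded partition; fold sizes differ by at most one.

## The model battery and synchronization models

Twelve togetherness models (1a–3d) cross three modality-specific predictor
sets with four participant groups (a semi-professionals, b novices, c
pianists, d clarinetists), each with participant random intercepts and
AR(1) within-series errors, fitted at the CV-selected lag. Significance is
flagged at α = 0.0125 — Bonferroni for four models per modality — and the
flag is exactly `p < 0.0125`.

The synchronization models (4a–d on AO, 5a–d on AV) relate the rating read
at each sync point's reference time (latest onset among both parts) plus
the selected lag to the asynchrony *magnitude* in ms, with participant
random intercepts; magnitude is the default predictor because a single
negative slope ("the smaller the asynchronies, the more together") is a
statement about magnitude, and a signed mode is available. Sync points are
treated as exchangeable within a trial; with slowly drifting rating noise
this understates the standard errors somewhat (a known limitation noted
below). An inestimable slope (all asynchronies equal) is flagged rather
than raised.

Variance inflation factors (VIF_j = 1/(1−R²_j) from regressing predictor j
on the others) are reported for the AV predictor set; collinearity between
local QoM per pair and pair powers is why total QoM, not local QoM, enters
the models.

## ANOVAs, body-part comparisons, eye-gaze

Per-trial mean ratings feed two factorial fixed-effects ANOVAs (type-II
sums of squares on the near-balanced design): music background × modality ×
stimulus group on the full data, and instrument × modality × stimulus group
on the semi-professionals. Tukey HSD pairwise contrasts are computed on the
requested factor (or crossed factor cells). Empty design cells are
reported, not silently ignored.

Body-part differences in local QoM and in cross-wavelet power are modelled
as response ~ body part with a stimulus random intercept and AR(1) errors
within each stimulus × part series; pairwise part contrasts use the
studentized-range (Tukey) distribution on the fitted covariance.

Eye-gaze fixation samples arrive already labelled with one of five areas of
interest (both musicians' heads and upper bodies, screen centre) — the
gaze-to-AOI assignment is an upstream manual step. Percentages are of
*tracked* samples within 1 s bins (they sum to 100% per bin), averaged over
bins with the partial final bin weighted by its wall-time coverage; the
per-participant × stimulus × AOI means feed a mixed model with AOI and
music training fixed and crossed participant and stimulus random
intercepts (statsmodels MixedLM variance components).

## The synthetic-data generator

The generator emulates the full study design — 2 stimulus groups × 8
performances × 3 modalities × 30 participants (10 novices, 10 pianists, 10
clarinetists), ~47 s stimuli — at any scale, with every true parameter in a
JSON manifest. Defaults, with units and rationale:

- **Motion** (240 Hz): each paired body part carries a shared sinusoid at
  the stimulus' base period (drawn from 0.8–2.5 s, the tempo range of slow
  expressive sway) with a slow common phase drift (SD 1.5 rad, ~2 s
  correlation — expressive timing), weighted by the coupling κ_part, plus a
  per-musician idiosyncratic sinusoid weighted (1−κ) whose period ranges
  are disjoint between the musicians (a duo's personal sway tempi differ),
  plus low-pass positional noise (0.5 mm, 150 ms correlation — mocap
  jitter that must not dominate the double derivative). Default amplitudes
  put the head highest (25 mm), arms next, chest lowest (6 mm); default
  couplings are moderate (0.3–0.7). Per-stimulus jitter of each part's
  amplitude (±30%) and coupling (±0.2) makes performances differ in *which*
  parts carried the coordination, which keeps the six pair-power predictors
  decorrelated across stimuli (low VIF, as real recordings show).
- **Note events**: 16 sync points per stimulus on an expressive-timing
  grid; sync points 11–14 are chords with 2–3 near-simultaneous notes per
  part. Secondo onsets are Primo plus Normal(0, σ_async) noise with
  σ_async = 159 ms (piano) and 172 ms (clarinet), chosen so the
  folded-normal mean |asynchrony| (σ√(2/π) ≈ 127 and 137 ms) matches the
  magnitudes observed in freely timed duo phrases.
- **Intensity**: three raised-cosine phrase arcs (13/15/18 shares of the
  duration) with exponential attack transients at the Primo's onsets,
  emitted at 10 Hz; optionally rendered as an amplitude-modulated sine tone
  whose windowed RMS recovers the curve (r > 0.95).
- **Ratings**: latent togetherness = 50 + group/modality offset +
  participant intercept (SD 5) + Σ β_group,j × lagged centred log-feature_j
  + AR(1) noise (marginal SD 5, ρ = 0.97 at the 100 ms step — a rating that
  drifts over seconds, not one that decorrelates within 100 ms), clipped to
  0–100. The log offsets and centring constants are pooled across stimuli,
  mirroring exactly how the model tables are built, so fitted coefficients
  are comparable with the generating weights on both the within- and
  between-stimulus axes. The true perceptual lag defaults to 1 s. Group
  weights default to the pattern the analysis is designed to detect:
  novices weight intensity (3.8 per log unit) and right-arm power (0.7);
  pianists and clarinetists weight chest power (0.5); clarinetists
  additionally weight asynchrony magnitude (−0.006 per ms). Modality masks
  hide audio features in VO and motion features in AO.
- **Emission**: a slider event is emitted at any 100 ms step at which the
  latent value has moved at least `slider_threshold` from the last emitted
  value. The default threshold is 0.5 rating units — nearly continuous
  tracking — because a wide deadband censors small feature-driven changes
  and attenuates every fitted slope toward zero (~30% at a deadband of 4);
  a threshold of ~4 instead reproduces the sparser ~1-change-per-1.1 s
  event density real slider logs show, at the cost of that attenuation.
  Users studying the emission process itself should raise the threshold
  knowingly.
- **Fixations**: a sticky Markov chain over the five AOIs plus off-AOI
  (mean dwell 0.5 s) with the Secondo's upper body attracting the most
  time.

What the generator does **not** emulate: biomechanics (markers are
independent oscillators, not a skeleton), polyphonic audio, score
structure beyond sync points, inter-rater idiosyncrasies beyond a random
intercept, blinks/tracking loss beyond the off-AOI state, and any
systematic relation between motion features and asynchronies (they are
independent by construction). Passing recovery tests therefore demonstrate
that the pipeline measures what it claims on data obeying its assumptions —
not that real audiences behave this way.

## Problem sizes used in tests and acceptance runs

The test suite and the acceptance script run the full pipeline at reduced
scale, as deliberate package defaults: recovery replicates use 6
participants, 4 stimuli and 20 s durations; the qualitative
pattern-reproduction study uses the full 2 × 8 × 3 design with 6
participants per expertise group and 30 s stimuli; the acceptance script
runs that same design with repeats included. Period grids are capped at
duration/2.2 so the largest wavelet always fits the series.

## Known limitations

- The cross-wavelet input is the acceleration *norm*, which rectifies the
  signal (energy moves to the doubled frequency and the amplitude
  envelope); a per-axis mode exists but is off by default. The smoothed
  cross modulus rewards phase-locking but is not a normalised coherence.
- The sync models assume exchangeable sync points; with rating noise that
  drifts over seconds, nominal standard errors there are somewhat
  optimistic.
- Between-stimulus confounding (asynchronies and features are fixed per
  stimulus and shared by all raters) limits the effective sample size of
  stimulus-level effects to the number of stimuli, not the number of rows.
- Wald inference with residual df; no Satterthwaite/Kenward–Roger
  correction (immaterial at these n, stated for small-data reuse).
- The rating emission model trades event-density realism for linear-model
  fidelity (see above); both regimes are one parameter away.
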