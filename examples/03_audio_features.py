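"""Audio features: RMS intensity, perceptual onsets, note asynchronies.

Renders a sine tone following a phrase-shaped intensity curve, recovers the
curve with the 10 Hz RMS envelope, estimates a perceptual onset at 70% of
the regional maximum RMS, and computes signed asynchronies (Secondo minus
Primo; positive = Primo leading) including the chord rule.
"""

import numpy as np

from duetsense import NoteEvent, note_asynchronies, perceptual_onset, rms_envelope
from duetsense.audio import summarize_asynchrony
from duetsense.simulate import SimulationConfig, render_audio, simulate_intensity, simulate_onsets

cfg = SimulationConfig(seed=5, duration=20.0)
events = simulate_onsets(cfg, "piano_01", n_sync=8, chords=(5,))
env = simulate_intensity(cfg, events, "piano_01")
audio = render_audio(env, cfg.duration, rate=22050)

measured = rms_envelope(audio, 22050)
n = min(len(measured.values), len(env.values))
r = np.corrcoef(measured.values[:n], env.values[:n])[0, 1]
print(f"RMS envelope recovers the programmed curve: r = {r:.3f}")

first = min(e.onset for e in events)
onset = perceptual_onset(audio, 22050, region=(max(first - 0.3, 0), first + 0.3))
print(f"perceptual onset near first note: {onset:.3f} s (scored {first:.3f} s)")

records = note_asynchronies(events)
mean_abs, sd = summarize_asynchrony(records)
print(f"mean |asynchrony| = {mean_abs:.1f} ms (SD {sd:.1f} ms) over "
      f"{len(records)} sync points")
print(
    "-> asynchronies on the order of 100-150 ms are typical of freely timed\n"
    "   duo phrases; the sign says which part sounded first."
)
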