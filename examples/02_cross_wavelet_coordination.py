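"""Cross-wavelet coordination of a coupled duo.

Simulates a duo whose head markers share a phase-drifting oscillation at a
1.5 s period, extracts the cross-wavelet power series at the dominant common
period, and contrasts it with a time-reversed surrogate in which the
coupling is destroyed but each musician's motion is unchanged.
"""

import numpy as np

from duetsense import DuoRecording, MarkerTrajectory, coordination_series
from duetsense.coordination import PeriodGrid
from duetsense.simulate import SimulationConfig, simulate_duo_motion

coupling = dict(SimulationConfig().coupling, head=0.95)
cfg = SimulationConfig(seed=1, duration=30.0, n_stimuli_per_group=1,
                       coupling=coupling, coupling_jitter=0.0)
rec = simulate_duo_motion(cfg, "piano_01")
grid = PeriodGrid.from_range(0.3, 7.0)

coord = coordination_series(rec, "head", grid=grid)
print(f"dominant common period: {coord.dominant_period:.2f} s")
print(f"median cross power:     {np.median(coord.power.values):.3g}")

markers = {k: v.positions.copy() for k, v in rec.trajectories.items()}
markers["S_head"] = markers["S_head"][::-1]  # destroy the alignment
surrogate = DuoRecording(
    "piano_01", "piano",
    {k: MarkerTrajectory(k, v, cfg.rate) for k, v in markers.items()},
)
surr = coordination_series(surrogate, "head", grid=grid)
ratio = np.median(coord.power.values) / np.median(surr.power.values)
print(f"surrogate power ratio:  {ratio:.2f}")
print(
    "-> a ratio well above 1 means the duo's heads share genuine phase-locked\n"
    "   periodic motion, not just energy at the same period."
)
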