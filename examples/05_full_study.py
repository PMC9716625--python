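"""End-to-end miniature study: generate, analyse, report.

Generates a miniature synthetic study (2 stimulus groups x 2 performances x
3 modalities x 6 participants, 20 s stimuli) with known ground truth, runs
the full pipeline, and prints the selected perceptual lag, the significant
togetherness-model effects, and the asynchrony summary.
"""

import tempfile

from duetsense import analyze_study, generate_study, miniature_config

cfg = miniature_config(seed=11)
with tempfile.TemporaryDirectory() as tmp:
    generate_study(cfg, f"{tmp}/study")
    analysis = analyze_study(f"{tmp}/study", k=6, seed=11)

print(f"selected perceptual lag: {analysis.selected_lag:.0f} s "
      f"(generated with {cfg.true_lag:.0f} s)")
sig = analysis.battery_table.query("significant")
print("significant battery effects (alpha = 0.0125):")
print(sig[["model", "group", "term", "beta", "p"]].round(4).to_string(index=False))
for group, (mean_abs, sd) in analysis.asynchrony_summary.items():
    print(f"{group}: mean |asynchrony| = {mean_abs:.0f} ms (SD {sd:.0f} ms)")
print(
    "-> model labels: 1=AO intensity, 2=VO motion, 3=AV both; letters are\n"
    "   participant groups (a semi-pro, b novice, c pianist, d clarinetist).\n"
    "   At this miniature scale (4 stimuli) a few spurious motion terms are\n"
    "   expected: stimulus-level features are shared by every rater, so their\n"
    "   effective n is the number of stimuli. scripts/acceptance.py runs the\n"
    "   full 2 x 8 x 3 design, where the generated pattern comes out cleanly."
)
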