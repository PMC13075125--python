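"""From landmarks to joint angles, gait cycles and kinematic parameters.

Renders a noise-free walk, computes the raw knee angle
arccos((B-A).(C-B)/|B-A||C-B|) from the hip-knee-ankle landmark triple,
segments gait cycles on the knee flexion maxima, and aggregates per-cycle
max/min/ROM into the session summary.
"""

import gaitmark as gm

waveforms = gm.make_gait_waveforms(gm.GaitWaveformConfig())
series, truth = gm.render_landmark_series(
    waveforms, gm.Anthropometry(), gm.NoiseModel(seed=0), duration=5.5, fps=30.0
)

spec = gm.joint_spec_for("knee", "right", series.side_convention)
print(f"right knee landmark triple (hip, knee, ankle): {spec.landmark_ids}")

raw = gm.joint_angle_series(series, spec)
knee = gm.to_anatomical(raw)
print(f"knee flexion range over the walk: "
      f"{knee.values.min():.2f} .. {knee.values.max():.2f} deg")

cycles = gm.segment_cycles(knee, min_prominence=15.0, min_period=0.6)
print(f"\ndetected {len(cycles)} gait cycles (5 rendered peaks -> 4 peak-to-peak cycles):")
params = []
for c in cycles:
    p = gm.cycle_parameters(knee, c)
    params.append(p)
    print(f"  frames [{c.start_frame:3d}, {c.end_frame:3d})  "
          f"max {p.max_deg:6.2f}  min {p.min_deg:5.2f}  rom {p.rom_deg:6.2f}")

summary = gm.session_summary(params, joint="knee", side="right")
true_max, true_min, true_rom = waveforms.extrema()[("knee", "right")]
print(f"\nsession means: flexion {summary.max_deg:.2f} (true {true_max}), "
      f"extension {summary.min_deg:.2f} (true {true_min}), "
      f"rom {summary.rom_deg:.2f} (true {true_rom})")
print("At 30 fps the peak can fall between frames, so recovered extrema sit "
      "within ~0.3 deg of truth; mean(rom) = mean(max) - mean(min) exactly.")
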