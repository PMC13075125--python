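"""Two-system agreement on a 27-subject cohort with a 3-degree offset.

Draws paired per-subject summaries for a reference system (wearable-like)
and an estimated system carrying a +3 deg systematic bias plus 2.6 deg
inter-system noise, then runs the full battery: normality-gated paired
test, Spearman rho, ICC(2,1), Bland-Altman and MAE.
"""

import gaitmark as gm

delta = 3.0
reference, estimated = gm.make_cohort(
    n_subjects=27,
    noise=gm.NoiseModel(angle_offset=delta, seed=1),
    n_sessions=2,
)
report = gm.compare_systems(reference, estimated)

print(f"{'parameter':<28} {'p':>6} {'test':<9} {'rho':>6} {'ICC':>6} "
      f"{'MAE':>5} {'bias':>5} {'LoA':>16}")
for r in report.rows:
    name = f"{r.side} {r.joint} {r.parameter}"
    loa = f"[{r.ba.loa_low:6.2f},{r.ba.loa_high:6.2f}]"
    print(f"{name:<28} {r.p_value:6.3f} {r.test_used:<9} {r.rho:6.3f} "
          f"{r.icc:6.3f} {r.mae_deg:5.2f} {r.ba.bias:5.2f} {loa:>16}")

row = next(r for r in report.rows
           if (r.joint, r.side, r.parameter) == ("knee", "right", "flexion_max"))
print(f"\ninjected offset: {delta} deg; recovered right-knee-flexion bias "
      f"{row.ba.bias:.2f} deg, 95% CI [{row.ba.ci_low:.2f}, {row.ba.ci_high:.2f}]")
print("The systematic offset shows up as the Bland-Altman bias while the high "
      "rank correlation shows the systems still order subjects identically; "
      "ICC (absolute agreement) is pulled down by the offset.")
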