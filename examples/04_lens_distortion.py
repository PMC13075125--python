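"""Effect of radial lens distortion on recovered angles, and its correction.

Renders the same walk through a camera with barrel distortion
(k1 = -0.1, k2 = 0.02), then analyzes the stream with and without the
undistortion stage and compares both to the analytic truth.
"""

import gaitmark as gm

camera = gm.CameraModel(fx=1000, fy=1000, cx=960, cy=540, k1=-0.1, k2=0.02)
waveforms = gm.make_gait_waveforms(gm.GaitWaveformConfig())
series, truth = gm.render_landmark_series(
    waveforms, gm.Anthropometry(), gm.NoiseModel(seed=3),
    duration=5.5, fps=30.0, camera=camera,
)


def max_error(camera_model):
    rows = gm.analyze_subject(
        "S01", [gm.analyze_series(series, camera=camera_model)]
    )
    return max(
        abs(r.value_deg - truth.entries[(r.joint, r.side, r.parameter)])
        for r in rows.itertuples()
    )


print(f"max parameter error without undistortion: {max_error(None):.3f} deg")
print(f"max parameter error with undistortion:    {max_error(camera):.3f} deg")
p = (1500.0, 900.0)
pd = gm.distort_point(camera, p)
pu = gm.undistort_point(camera, pd)
print(f"\npoint {p} -> distorted ({pd[0]:.2f}, {pd[1]:.2f}) "
      f"-> undistorted ({pu[0]:.6f}, {pu[1]:.6f})")
print("Undistortion inverts the radial model to sub-1e-6 px, restoring the "
      "geometry the angle formulas assume.")
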