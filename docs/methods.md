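# Methods

This note documents the models, conventions and numerical choices behind
`gaitmark`, and what its synthetic validation does and does not
demonstrate.

## Joint-angle model

A sagittal joint angle is defined on an ordered landmark triple (A, B, C)
as the turning angle between the proximal segment vector A→B and the
distal segment vector B→C:

    θ = arccos( (B−A)·(C−B) / (|B−A| |C−B|) ) ∈ [0°, 180°].

* **Knee** (hip–knee–ankle): θ is the flexion angle directly; 0° is a
  straight leg. The "extension" parameter reported per cycle is the
  *minimum* of θ, i.e. residual flexion at the straightest point — with
  this reading ROM = flexion − extension holds additively, which is the
  convention the aggregation identities rely on. Signed hyperextension is
  not represented.
* **Ankle** (knee–ankle–toe): the anatomical angle is 90° − θ, positive
  dorsiflexion, negative plantarflexion. The neutral reference at
  θ = 90° is a modelling choice; because it is a fixed offset it cancels
  in every ROM, so only the dorsi/plantar split — not any range — depends
  on it. The "plantarflexion" parameter is reported as the magnitude of
  the most negative angle, so ankle ROM = dorsiflexion + plantarflexion.

The arccos argument is clamped to [−1, 1] to absorb rounding; zero-length
segments raise a degenerate-geometry error rather than returning NaN. The
angle is invariant under translation, rotation, reflection and uniform
scaling (verified to < 1e−9° under random similarity transforms), which is
what makes it computable in pixel coordinates. Normalized (0–1)
coordinates are anisotropic — x and y are divided by different image
dimensions — and are therefore always converted back to pixels before any
angle is computed.

**Visibility gaps.** Landmarks with visibility < 0.5 are linearly
interpolated across runs of at most 5 frames (runs touching the series
edge are held at the nearest confident value); longer runs raise an error
naming the frame range. This conservative policy keeps angles well
defined without inventing motion over long occlusions.

**Smoothing** (centered moving average, odd window, edges shrunk
symmetrically) is available but off by default: on noisy streams it
trades extreme-value noise bias for attenuation of the narrow
plantarflexion and swing peaks, and at 30 fps the attenuation loss
dominates for windows ≥ 5 frames.

## Camera model

Lens distortion follows the standard two-term radial model in normalized
image coordinates about the principal point, `factor = 1 + k1 r² + k2 r⁴`.
Undistortion inverts it by fixed-point iteration
(`x_u ← x_d / factor(x_u)`, tolerance 1e−9 normalized units, ≤ 100
iterations), which converges for the moderate distortion of consumer
lenses (|k1 r²| well below 1); the round trip closes to < 1e−6 px over a
full-HD field at k1 = −0.1, k2 = 0.02. Tangential terms are omitted —
checkerboard calibrations of phone cameras rarely report meaningful ones —
and extrinsics, if present in a camera config, are stored but unused:
summary-level sagittal angles need no metric reconstruction. Zero
distortion is a bit-exact identity, so inserting the camera stage with
k1 = k2 = 0 changes nothing downstream. The stage corrects landmark
*coordinates*; correcting whole images before pose estimation is an
upstream alternative this library cannot perform.

## Gait cycles and aggregation

Cycles are anchored on knee swing-phase flexion maxima: local maxima with
prominence ≥ 15° separated by ≥ 0.6 s (scipy `find_peaks`), consecutive
peaks delimiting half-open [start, end) cycles; k peaks give k−1 cycles
and incomplete leading/trailing partials are discarded. The defaults are
conservative for healthy adult cadence and keep the early-stance flexion
bump (≈ 10° prominence) from splitting strides; both are exposed. Ankle
parameters are computed over the knee-defined cycles of the same limb, so
one walk yields one temporal partition per side.

Aggregation is unweighted at every level: per-cycle (max, min,
ROM = max − min) → session mean over cycles → subject mean over sessions.
Because every step is a mean, mean(ROM) = mean(max) − mean(min) holds
exactly (to linearity of the mean) all the way up; sessions with fewer
than three cycles are flagged rather than rejected.

## Agreement battery

For each parameter, per-subject paired values (reference, estimated):

* **Location test.** Shapiro–Wilk on the differences at α = 0.05 gates a
  two-sided paired t-test (normal) vs the Wilcoxon signed-rank test.
  Wilcoxon drops zero differences, uses mean ranks for tied magnitudes,
  the exact null distribution for n ≤ 25 without ties and the normal
  approximation with continuity correction otherwise. Perfectly constant
  nonzero differences skip the (undefined) normality gate and go to the
  signed-rank branch; all-zero differences are reported as degenerate
  with a NaN p-value instead of a fabricated one. No multiple-testing
  correction is applied; α holds per test.
* **Spearman ρ** — Pearson correlation of mean ranks; undefined (error)
  when either system has zero rank variance.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure, from the ANOVA mean squares:
  (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n). The absolute-agreement
  form is deliberately offset-sensitive: a constant inter-system shift
  lowers it below the consistency form. The model/type choice is a
  documented convention of this package, matched in tests against an
  independent ANOVA implementation to 1e−10.
* **Bland–Altman** — differences d (default estimated − reference;
  configurable, since the direction convention is not universal), bias =
  mean(d), SD with n−1 denominator, limits of agreement bias ± 1.96·SD,
  bias CI bias ± 1.96·SD/√n. The normal 1.96 multiplier (not t) is used
  for both, matching the convention under which published bias bounds at
  n = 27 reconstruct exactly; at that n it yields ≈ 94% rather than 95%
  realized CI coverage, which the seeded coverage checks reflect.
* **MAE** — mean |estimated − reference|.
* **Bands** for ρ and ICC: poor < 0.500 ≤ moderate ≤ 0.750 < good ≤
  0.900 < excellent; negative values are poor.

Report tables keep full precision internally; the formatted view rounds
half-up to two decimals as printed tables do.

## Synthetic gait generator

The generator replaces video and wearable recordings with a controlled
emulation. What it emulates: a lateral 1920×1080 view at ~30 fps of a
walker covering ≥ 3 gait cycles per session, two sessions per subject,
cohorts of 27 subjects whose group kinematics sit at healthy-adult scale
(knee flexion ≈ 47–51°, extension ≈ 6–7°, dorsiflexion ≈ 12–20°,
plantarflexion ≈ 17–20°), with controllable pixel noise, visibility
dropout and inter-system bias.

* **Waveforms.** Each joint angle over a cycle is a periodic chain of
  raised-cosine arcs through fixed (phase, value) nodes — knee: minimum
  at heel strike, stance bump at 15% cycle, minimum at 40%, swing peak at
  72%; ankle: neutral, dorsiflexion peak at 45%, plantarflexion peak at
  62%, neutral from 85%. Each arc is monotone with zero end slopes, so
  the configured node values *are* the exact extrema — ground truth is
  closed-form, the design priority. Real knee/ankle curves differ in
  shape; only statistical-scale agreement with published group values is
  claimed, never curve-level fidelity.
* **Stick figure.** Segment lengths default to standard anthropometric
  fractions of a 1.70 m stature (thigh 0.245, shank 0.246, foot 0.152);
  the hip advances at 1.2 m/s at fixed height, and the thigh swings
  sinusoidally ±25° about vertical. These values shape the rendered
  geometry but cannot affect angle correctness, since the joint angles
  are imposed directly and the angle measure is similarity-invariant.
  The left limb is the right limb shifted by half a cycle (symmetric
  healthy gait).
* **Projection.** Orthographic (220 px/m, principal-point offset, pixel
  y down) — a lateral view from ~3 m is near-planar, and perspective
  would break the closed-form truth. Optional radial distortion is
  applied in the forward direction so the correction stage is exercised.
* **Noise.** Isotropic Gaussian pixel noise per landmark per frame;
  dropout marks a landmark low-visibility (0.1) with the configured
  probability. All randomness flows from an explicit seed; identical
  seeds give byte-identical streams.
* **Cohorts.** Per-subject parameters are drawn from population normals
  (defaults at published wearable-system group means/SDs); reference ROM
  is derived from the drawn extrema. Sessions add 1.5° jitter; each
  estimated parameter is its reference value + angle_offset + 2.6°
  independent error (the 2.6° matches the difference-SD scale
  reconstructed from published knee-extension limits of agreement). The
  offset is applied per parameter — emulating a device that reports each
  parameter as its own measurement — so it is recoverable as the
  Bland–Altman bias of every parameter, ROM included.

## Numerical behaviour and verified bounds

* Dense 10⁴-point sampling reproduces configured extrema to < 1e−3°.
* Full pipeline on noise-free renders recovers every parameter within
  0.1° at 120 fps and 0.5° at 30 fps — the residual is pure
  peak-sampling error (≤ amplitude·(π·Δφ/2)²/... ≈ 0.3° for a half-frame
  phase offset on the narrowest default lobe at 30 fps).
* With pixel noise, per-cycle extremes are biased outward by ~2–3× the
  per-frame angle noise (≈ 1° per 1 px on ~90 px segments); this is an
  intrinsic property of extremum statistics under noise, not a pipeline
  defect, and is why ROM under noise is slightly inflated.
* Injected inter-system offsets are recovered as Bland–Altman bias with
  CI coverage consistent with the ≈ 94% realized coverage noted above.

## What passing tests do not show

The generator's waveform shapes, orthographic camera and Gaussian noise
are idealizations: real pose-estimation error is structured (limb
confusion, occlusion, depth-dependent scale), real gait is asymmetric and
variable cycle-to-cycle, and real validation cohorts disagree between
devices for physiological as well as algorithmic reasons. Passing the
synthetic acceptance suite demonstrates that the *implementation* is
correct and self-consistent at realistic scales — not that any particular
camera system achieves a given accuracy on humans. Published
real-cohort agreement values (e.g. MAE ≈ 3–5° for knee parameters) are
not reproducible without the original recordings and are not targets of
this package's tests; only the internally reproducible arithmetic of such
reports (ROM identities, CI reconstruction) is checked.

## Known limitations

* Sagittal plane only; no hip kinematics, no 3D angles, no gait events
  (heel strike/toe off) or spatio-temporal parameters.
* Peak-to-peak segmentation assumes a dominant swing peak; severely
  pathological or shuffling gait would need different anchors.
* The camera stage models radial distortion only and assumes coordinates
  can be corrected post hoc.
* `side_convention` must be supplied correctly by the producer of the
  landmark file; the library supports both conventions but cannot detect
  which one a stream uses.
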