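"""Synthetic planar gait: waveforms, stick-figure kinematics, rendering.

Real validation studies record walking subjects on video and with wearable
sensors; neither stream can ship with a library. This module replaces them
with a fully controlled emulation whose ground truth is known in closed
form:

1. **Waveforms** — per joint, a periodic piecewise raised-cosine template
   interpolating a small set of (phase, angle) nodes. Each segment is
   monotone, so the template's extrema are exactly the configured node
   values: the true max, min and ROM of every joint are analytic, not
   estimated. The knee template has an early-stance flexion bump and a
   dominant swing peak; the ankle template has a dorsiflexion lobe in late
   stance and a plantarflexion lobe at push-off. Amplitudes default to the
   scale reported for healthy adults (swing peak ~50 deg, residual
   extension ~6-7 deg, dorsiflexion ~15 deg, plantarflexion ~18 deg).
2. **Forward kinematics** — a sagittal stick figure (hip, knee, ankle,
   toe per side) with fixed segment lengths driven by the waveforms; the
   left limb is the right limb phase-shifted by half a cycle (symmetric
   healthy gait). The hip advances at constant walking speed.
3. **Rendering** — orthographic projection (px per metre, principal-point
   offset, pixel y down) onto a 1920x1080 frame at a configurable frame
   rate, with optional radial lens distortion, isotropic Gaussian pixel
   noise and visibility dropout. Same seed, same bytes.
4. **Cohorts** — paired per-subject summary tables for a reference system
   and an estimated system, the estimated values carrying a configurable
   systematic offset and inter-system noise, for exercising the agreement
   statistics at realistic population scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .camera import CameraModel, distort_points
from .errors import ValidationError
from .landmarks import CONVENTIONS, LandmarkSeries

_SIDES = ("right", "left")

# knee template node phases: heel strike, stance bump, mid-stance minimum,
# swing peak, next heel strike
_KNEE_PHASES = (0.0, 0.15, 0.40, 0.72, 1.0)
# ankle template node phases: neutral, dorsiflexion peak (late stance),
# plantarflexion peak (push-off), return to neutral, hold
_ANKLE_PHASES = (0.0, 0.45, 0.62, 0.85, 1.0)


@dataclass(frozen=True)
class GaitWaveformConfig:
    """Target angles (degrees) and timing of the periodic gait templates."""

    cycle_duration: float = 1.1
    knee_swing_peak: float = 50.0
    knee_stance_peak: float = 16.0
    knee_min: float = 6.5
    ankle_dorsi_peak: float = 15.0
    ankle_plantar_peak: float = 18.0
    left_phase_offset: float = 0.5

    def __post_init__(self) -> None:
        for name in ("cycle_duration", "knee_swing_peak", "knee_stance_peak",
                     "knee_min", "ankle_dorsi_peak", "ankle_plantar_peak",
                     "left_phase_offset"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"{name} must be finite, got {v}")
        if self.cycle_duration <= 0:
            raise ValidationError(f"cycle_duration must be > 0, got {self.cycle_duration}")
        if not self.knee_swing_peak > self.knee_stance_peak:
            raise ValidationError(
                f"knee_swing_peak ({self.knee_swing_peak}) must exceed "
                f"knee_stance_peak ({self.knee_stance_peak})"
            )
        if not self.knee_stance_peak >= self.knee_min:
            raise ValidationError(
                f"knee_stance_peak ({self.knee_stance_peak}) must be >= "
                f"knee_min ({self.knee_min})"
            )
        if self.knee_min < 0:
            raise ValidationError(f"knee_min must be >= 0, got {self.knee_min}")
        if self.ankle_dorsi_peak < 0:
            raise ValidationError(f"ankle_dorsi_peak must be >= 0, got {self.ankle_dorsi_peak}")
        if self.ankle_plantar_peak < 0:
            raise ValidationError(
                f"ankle_plantar_peak must be >= 0, got {self.ankle_plantar_peak}"
            )
        if not 0 <= self.left_phase_offset < 1:
            raise ValidationError(
                f"left_phase_offset must lie in [0, 1), got {self.left_phase_offset}"
            )

    def to_dict(self) -> dict:
        return {
            "cycle_duration": self.cycle_duration,
            "knee_swing_peak": self.knee_swing_peak,
            "knee_stance_peak": self.knee_stance_peak,
            "knee_min": self.knee_min,
            "ankle_dorsi_peak": self.ankle_dorsi_peak,
            "ankle_plantar_peak": self.ankle_plantar_peak,
            "left_phase_offset": self.left_phase_offset,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GaitWaveformConfig":
        return cls(**dict(d))


class PiecewiseRaisedCosine:
    """Periodic function through (phase, value) nodes via raised-cosine arcs.

    Between consecutive nodes the function is
    ``v0 + (v1 - v0) * (1 - cos(pi*s)) / 2`` with s the within-segment
    fraction — monotone with zero slope at both ends, so every local
    extremum of the composite curve is exactly a node value.
    """

    def __init__(self, phases, values):
        phases = np.asarray(phases, dtype=float)
        values = np.asarray(values, dtype=float)
        if phases[0] != 0.0 or phases[-1] != 1.0 or np.any(np.diff(phases) <= 0):
            raise ValidationError("node phases must increase strictly from 0 to 1")
        if len(phases) != len(values):
            raise ValidationError("phases and values must have equal length")
        self.phases = phases
        self.values = values

    def __call__(self, phase):
        p = np.mod(np.asarray(phase, dtype=float), 1.0)
        idx = np.clip(np.searchsorted(self.phases, p, side="right") - 1, 0, len(self.phases) - 2)
        p0 = self.phases[idx]
        p1 = self.phases[idx + 1]
        v0 = self.values[idx]
        v1 = self.values[idx + 1]
        s = (p - p0) / (p1 - p0)
        return v0 + (v1 - v0) * 0.5 * (1.0 - np.cos(np.pi * s))

    @property
    def true_max(self) -> float:
        return float(self.values.max())

    @property
    def true_min(self) -> float:
        return float(self.values.min())


@dataclass
class JointWaveforms:
    """Per-joint periodic angle functions with closed-form extrema.

    ``knee`` is the anatomical knee flexion angle (degrees, >= 0) and
    ``ankle`` the anatomical ankle angle (positive dorsiflexion) for the
    right limb as functions of cycle phase; the left limb uses the same
    templates shifted by ``left_phase_offset`` cycles.
    """

    knee: Callable[[np.ndarray], np.ndarray]
    ankle: Callable[[np.ndarray], np.ndarray]
    cycle_duration: float
    left_phase_offset: float
    knee_extrema: tuple[float, float]   # (true_max, true_min)
    ankle_extrema: tuple[float, float]

    def phase(self, t, side: str = "right") -> np.ndarray:
        p = np.asarray(t, dtype=float) / self.cycle_duration
        if side == "left":
            p = p - self.left_phase_offset
        elif side != "right":
            raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
        return p

    def knee_angle(self, t, side: str = "right") -> np.ndarray:
        return self.knee(self.phase(t, side))

    def ankle_angle(self, t, side: str = "right") -> np.ndarray:
        return self.ankle(self.phase(t, side))

    def extrema(self) -> dict[tuple[str, str], tuple[float, float, float]]:
        """(true_max, true_min, true_rom) per (joint, side)."""
        out = {}
        for joint, (mx, mn) in (("knee", self.knee_extrema), ("ankle", self.ankle_extrema)):
            for side in _SIDES:
                out[(joint, side)] = (mx, mn, mx - mn)
        return out


def make_gait_waveforms(config: GaitWaveformConfig) -> JointWaveforms:
    """Build the periodic joint-angle templates from a validated config."""
    knee = PiecewiseRaisedCosine(
        _KNEE_PHASES,
        (config.knee_min, config.knee_stance_peak, config.knee_min,
         config.knee_swing_peak, config.knee_min),
    )
    ankle = PiecewiseRaisedCosine(
        _ANKLE_PHASES,
        (0.0, config.ankle_dorsi_peak, -config.ankle_plantar_peak, 0.0, 0.0),
    )
    return JointWaveforms(
        knee=knee,
        ankle=ankle,
        cycle_duration=config.cycle_duration,
        left_phase_offset=config.left_phase_offset,
        knee_extrema=(knee.true_max, knee.true_min),
        ankle_extrema=(ankle.true_max, ankle.true_min),
    )


@dataclass(frozen=True)
class Anthropometry:
    """Segment lengths and gait speed of the simulated walker (metres, m/s).

    Defaults follow standard anthropometric segment fractions of a 1.70 m
    stature (thigh 0.245, shank 0.246, foot 0.152 of stature); the exact
    values do not affect angle correctness, only the rendered geometry.
    """

    thigh_length: float = 0.245 * 1.70
    shank_length: float = 0.246 * 1.70
    foot_length: float = 0.152 * 1.70
    hip_height: float = 0.90
    walking_speed: float = 1.2

    def __post_init__(self) -> None:
        for name in ("thigh_length", "shank_length", "foot_length",
                     "hip_height", "walking_speed"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def from_stature(cls, stature: float = 1.70, walking_speed: float = 1.2) -> "Anthropometry":
        if stature <= 0:
            raise ValidationError(f"stature must be > 0, got {stature}")
        return cls(
            thigh_length=0.245 * stature,
            shank_length=0.246 * stature,
            foot_length=0.152 * stature,
            hip_height=0.53 * stature,
            walking_speed=walking_speed,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise knobs for the renderer and cohort generator."""

    pixel_sd: float = 0.0
    angle_offset: float = 0.0
    visibility_dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_sd < 0:
            raise ValidationError(f"pixel_sd must be >= 0, got {self.pixel_sd}")
        if not 0 <= self.visibility_dropout_rate < 1:
            raise ValidationError(
                f"visibility_dropout_rate must lie in [0, 1), got {self.visibility_dropout_rate}"
            )


def _rotate(vx: np.ndarray, vy: np.ndarray, angle_rad: np.ndarray):
    c = np.cos(angle_rad)
    s = np.sin(angle_rad)
    return vx * c - vy * s, vx * s + vy * c


def _leg_points(
    waveforms: JointWaveforms,
    anthropometry: Anthropometry,
    t: np.ndarray,
    side: str,
    angle_offset: float = 0.0,
    hip_sweep_deg: float = 25.0,
) -> dict[str, np.ndarray]:
    """World-frame (x forward, y up, metres) positions of one limb.

    The thigh swings sinusoidally about vertical with amplitude
    ``hip_sweep_deg`` (realism only — joint angles are set by the
    waveforms, not by the thigh's global orientation). The shank is the
    thigh direction rotated backwards by the knee flexion angle; the foot
    is the shank direction rotated forwards by the raw ankle angle
    theta2 = 90 deg - anatomical angle.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    phase = waveforms.phase(t, side)
    alpha = np.radians(hip_sweep_deg * np.cos(2 * np.pi * phase))
    knee_flex = np.radians(np.asarray(waveforms.knee(phase)) + angle_offset)
    ankle_anat = np.asarray(waveforms.ankle(phase)) + angle_offset
    theta2 = np.radians(90.0 - ankle_anat)

    hip = np.column_stack([anthropometry.walking_speed * t,
                           np.full_like(t, anthropometry.hip_height)])
    thigh_x, thigh_y = np.sin(alpha), -np.cos(alpha)
    shank_x, shank_y = _rotate(thigh_x, thigh_y, -knee_flex)
    foot_x, foot_y = _rotate(shank_x, shank_y, theta2)

    knee = hip + anthropometry.thigh_length * np.column_stack([thigh_x, thigh_y])
    ankle = knee + anthropometry.shank_length * np.column_stack([shank_x, shank_y])
    toe = ankle + anthropometry.foot_length * np.column_stack([foot_x, foot_y])
    return {"hip": hip, "knee": knee, "ankle": ankle, "toe": toe}


def forward_kinematics(
    waveforms: JointWaveforms,
    anthropometry: Anthropometry,
    t,
) -> dict[str, dict[str, np.ndarray]]:
    """Planar hip/knee/ankle/toe positions (m) for both limbs at time t.

    ``t`` may be a scalar or an array; positions come back as arrays of
    shape ``(n, 2)`` keyed by side then landmark role.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.isfinite(t_arr).all():
        raise ValidationError("t must be finite")
    return {side: _leg_points(waveforms, anthropometry, t_arr, side) for side in _SIDES}


_DEFAULT_CAMERA = dict(fx=1000.0, fy=1000.0, cx=960.0, cy=540.0,
                       image_width=1920, image_height=1080)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic per-parameter truth for a rendered stream.

    ``entries`` maps (joint, side, parameter) to degrees and reflects the
    stream as rendered, i.e. *including* any injected ``angle_offset``
    (max and min shift by the offset; ROM is unaffected). The offset is
    recorded so the unbiased reference truth can be recovered.
    """

    entries: dict[tuple[str, str, str], float]
    angle_offset: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"joint": j, "side": s, "parameter": p, "value_deg": v}
            for (j, s, p), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["joint", "side", "parameter", "value_deg"])

    def reference_entries(self) -> dict[tuple[str, str, str], float]:
        """Truth with the injected offset removed (ROM untouched)."""
        out = {}
        for (j, s, p), v in self.entries.items():
            if p == "rom":
                out[(j, s, p)] = v
            elif p == "plantarflexion":
                out[(j, s, p)] = v + self.angle_offset
            else:
                out[(j, s, p)] = v - self.angle_offset
        return out


def _truth_entries(waveforms: JointWaveforms, angle_offset: float) -> dict:
    entries = {}
    for (joint, side), (mx, mn, rom) in waveforms.extrema().items():
        if joint == "knee":
            entries[(joint, side, "flexion_max")] = mx + angle_offset
            entries[(joint, side, "extension_min")] = mn + angle_offset
        else:
            entries[(joint, side, "dorsiflexion")] = mx + angle_offset
            entries[(joint, side, "plantarflexion")] = -(mn + angle_offset)
        entries[(joint, side, "rom")] = rom
    return entries


def render_landmark_series(
    waveforms: JointWaveforms,
    anthropometry: Anthropometry,
    noise: NoiseModel,
    duration: float,
    fps: float,
    camera: CameraModel | None = None,
    px_per_m: float = 220.0,
    camera_height: float = 0.9,
    side_convention: str = "paper",
) -> tuple[LandmarkSeries, GroundTruth]:
    """Render a lateral-view landmark stream plus its analytic truth.

    The walk is centred in the image horizontally; the vertical axis maps
    world height to pixel rows through the camera height (pixel y grows
    downward). If ``camera`` carries distortion coefficients the forward
    radial model is applied, so the stream tests the undistortion stage.
    ``duration`` must cover at least three gait cycles.
    """
    if fps <= 0:
        raise ValidationError(f"fps must be > 0, got {fps}")
    min_duration = 3 * waveforms.cycle_duration
    if duration < min_duration:
        raise ValidationError(
            f"duration {duration} s too short: at least 3 gait cycles "
            f"({min_duration} s) are required"
        )
    if camera is None:
        camera = CameraModel(**_DEFAULT_CAMERA)
    n = int(math.floor(duration * fps))
    t = np.arange(n) / fps
    rng = np.random.default_rng(noise.seed)
    table = CONVENTIONS[side_convention]
    x_mid = anthropometry.walking_speed * duration / 2.0

    coords: dict[int, np.ndarray] = {}
    visibility: dict[int, np.ndarray] = {}
    for side in _SIDES:
        pts = _leg_points(waveforms, anthropometry, t, side, noise.angle_offset)
        for role in ("hip", "knee", "ankle", "toe"):
            lid = table[(role, side)]
            world = pts[role]
            px = np.empty_like(world)
            px[:, 0] = camera.cx + px_per_m * (world[:, 0] - x_mid)
            px[:, 1] = camera.cy + px_per_m * (camera_height - world[:, 1])
            if camera.has_distortion:
                px = distort_points(camera, px)
            if noise.pixel_sd > 0:
                px = px + rng.normal(0.0, noise.pixel_sd, size=px.shape)
            coords[lid] = px
            dropped = rng.random(n) < noise.visibility_dropout_rate
            visibility[lid] = np.where(dropped, 0.1, 1.0)

    series = LandmarkSeries.from_arrays(
        coords,
        visibility,
        fps=fps,
        coordinate_mode="pixel",
        image_width=camera.image_width,
        image_height=camera.image_height,
        side_convention=side_convention,
    )
    truth = GroundTruth(_truth_entries(waveforms, noise.angle_offset), noise.angle_offset)
    return series, truth


#: reference-system population marginals (mean, SD) in degrees for a
#: healthy adult cohort; ROM is derived per subject, never drawn.
DEFAULT_POPULATION: dict[tuple[str, str, str], tuple[float, float]] = {
    ("knee", "right", "flexion_max"): (49.18, 14.47),
    ("knee", "right", "extension_min"): (7.26, 4.31),
    ("ankle", "right", "dorsiflexion"): (14.86, 3.93),
    ("ankle", "right", "plantarflexion"): (16.92, 7.92),
    ("knee", "left", "flexion_max"): (47.45, 10.31),
    ("knee", "left", "extension_min"): (6.80, 3.40),
    ("ankle", "left", "dorsiflexion"): (12.48, 3.19),
    ("ankle", "left", "plantarflexion"): (20.17, 7.32),
}


def make_cohort(
    n_subjects: int = 27,
    population: Mapping[tuple[str, str, str], tuple[float, float]] | None = None,
    noise: NoiseModel = NoiseModel(),
    n_sessions: int = 2,
    inter_system_sd: float = 2.6,
    session_sd: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired per-subject summary tables for two measurement systems.

    Per subject, each base parameter is drawn from its population normal
    (knee extension resampled until below flexion; ankle peaks resampled
    until positive) and the reference ROM is derived from the drawn
    extrema, so the reference table is internally consistent. Per session,
    reference values get session-to-session jitter (``session_sd``); each
    estimated parameter — ROM included — is the corresponding reference
    value plus the systematic ``noise.angle_offset`` plus independent
    homoscedastic error (``inter_system_sd``), mimicking a second device
    that reports every parameter as its own measurement. Session values
    are averaged into the overall per-subject mean. Returns
    ``(reference, estimated)`` tidy tables.
    """
    if n_subjects < 3:
        raise ValidationError(f"n_subjects must be >= 3, got {n_subjects}")
    if n_sessions < 1:
        raise ValidationError(f"n_sessions must be >= 1, got {n_sessions}")
    if inter_system_sd < 0 or session_sd < 0:
        raise ValidationError("noise SDs must be >= 0")
    pop = dict(DEFAULT_POPULATION if population is None else population)
    for (joint, side, param), (mean, sd) in pop.items():
        if sd < 0:
            raise ValidationError(f"SD for {(joint, side, param)} must be >= 0, got {sd}")
    rng = np.random.default_rng(noise.seed)
    sides = sorted({side for (_, side, _) in pop})

    ref_rows, est_rows = [], []
    for i in range(n_subjects):
        subject = f"S{i + 1:02d}"
        for side in sides:
            for joint, lo_name, hi_name in (
                ("knee", "extension_min", "flexion_max"),
                ("ankle", "plantarflexion", "dorsiflexion"),
            ):
                hi_mean, hi_sd = pop[(joint, side, hi_name)]
                lo_mean, lo_sd = pop[(joint, side, lo_name)]
                for _ in range(100):
                    hi = rng.normal(hi_mean, hi_sd)
                    lo = rng.normal(lo_mean, lo_sd)
                    if joint == "knee" and 0 <= lo < hi:
                        break
                    if joint == "ankle" and lo > 0 and hi > 0:
                        break
                else:
                    raise ValidationError(
                        f"could not draw admissible {joint} parameters for {subject}; "
                        f"population means/SDs implausible"
                    )
                # per-session extrema for the reference system; ROM derived
                ref_hi = hi + rng.normal(0.0, session_sd, n_sessions)
                ref_lo = lo + rng.normal(0.0, session_sd, n_sessions)
                ref_rom = ref_hi - ref_lo if joint == "knee" else ref_hi + ref_lo
                ref_vals = {hi_name: ref_hi, lo_name: ref_lo, "rom": ref_rom}
                for name, ref_sessions in ref_vals.items():
                    est_sessions = (
                        ref_sessions
                        + noise.angle_offset
                        + rng.normal(0.0, inter_system_sd, n_sessions)
                    )
                    common = {"subject": subject, "joint": joint, "side": side,
                              "parameter": name}
                    ref_rows.append({**common, "value_deg": float(np.mean(ref_sessions))})
                    est_rows.append({**common, "value_deg": float(np.mean(est_sessions))})
    cols = ["subject", "joint", "side", "parameter", "value_deg"]
    return pd.DataFrame(ref_rows, columns=cols), pd.DataFrame(est_rows, columns=cols)


def subject_waveform_config(
    rng: np.random.Generator,
    base: GaitWaveformConfig | None = None,
) -> GaitWaveformConfig:
    """Draw a plausible per-subject waveform config around a base template.

    Peaks vary with healthy-cohort spreads (swing ~N(base, 8), extension
    ~N(base, 2) clipped to [0, ...], ankle peaks ~N(base, 3.5)); the
    stance bump tracks the drawn minimum at +9 deg so cycle segmentation
    sees a single dominant peak per stride.
    """
    base = base or GaitWaveformConfig()
    knee_min = float(np.clip(rng.normal(base.knee_min, 2.0), 0.0, 15.0))
    swing = float(np.clip(rng.normal(base.knee_swing_peak, 8.0), knee_min + 20.0, 80.0))
    dorsi = float(np.clip(rng.normal(base.ankle_dorsi_peak, 3.5), 2.0, 35.0))
    plantar = float(np.clip(rng.normal(base.ankle_plantar_peak, 3.5), 2.0, 35.0))
    cycle = float(np.clip(rng.normal(base.cycle_duration, 0.07), 0.8, 1.5))
    return replace(
        base,
        cycle_duration=cycle,
        knee_swing_peak=swing,
        knee_stance_peak=knee_min + 9.0,
        knee_min=knee_min,
        ankle_dorsi_peak=dorsi,
        ankle_plantar_peak=plantar,
    )
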