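"""Gait-cycle segmentation and the cycle -> session -> subject aggregation.

A walk is partitioned into cycles anchored on the knee swing-phase flexion
maxima — the most prominent, landmark-free event in the sagittal knee
curve. Consecutive qualifying peaks delimit half-open [start, end) cycles
(k peaks give k-1 cycles); incomplete leading/trailing partials are
discarded. Ankle parameters are computed over the knee-defined cycles of
the same limb so that one walk yields one consistent temporal partition.

Per cycle the kinematic parameters are the maximum angle, the minimum
angle, and the ROM (their difference). Cycle parameters are averaged
within a walking session (mean1, mean2, ...), and session means are
averaged into the per-subject overall mean. All aggregation is unweighted,
so mean(ROM) = mean(max) - mean(min) holds exactly at every level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import NoCyclesError, ValidationError
from .kinematics import AngleSeries

#: parameter naming used in summary tables, by joint
KNEE_PARAMS = ("flexion_max", "extension_min", "rom")
ANKLE_PARAMS = ("dorsiflexion", "plantarflexion", "rom")


@dataclass(frozen=True)
class GaitCycle:
    """Half-open frame interval [start_frame, end_frame) of one stride."""

    start_frame: int
    end_frame: int
    anchor_peak_frame: int

    def __post_init__(self) -> None:
        if not self.start_frame < self.end_frame:
            raise ValidationError(
                f"cycle must satisfy start < end, got [{self.start_frame}, {self.end_frame})"
            )
        if not (self.start_frame <= self.anchor_peak_frame < self.end_frame):
            raise ValidationError("anchor peak must lie within the cycle")


@dataclass(frozen=True)
class CycleParams:
    """Max, min and ROM of a joint angle over one cycle (degrees)."""

    max_deg: float
    min_deg: float
    rom_deg: float | None = None

    def __post_init__(self) -> None:
        if self.max_deg < self.min_deg:
            raise ValidationError(f"max {self.max_deg} < min {self.min_deg}")
        rom = self.max_deg - self.min_deg
        if self.rom_deg is None:
            object.__setattr__(self, "rom_deg", rom)
        elif abs(self.rom_deg - rom) > 1e-9:
            raise ValidationError(
                f"rom_deg {self.rom_deg} inconsistent with max - min = {rom}"
            )


@dataclass(frozen=True)
class SessionSummary:
    """Cycle-averaged parameters for one joint/side in one walking session."""

    joint: str
    side: str
    max_deg: float
    min_deg: float
    rom_deg: float
    n_cycles: int
    few_cycles: bool  # set when fewer than 3 cycles were available


@dataclass(frozen=True)
class SubjectSummary:
    """Session-averaged (overall mean) parameters for one joint/side."""

    joint: str
    side: str
    max_deg: float
    min_deg: float
    rom_deg: float
    n_sessions: int


def segment_cycles(
    series: AngleSeries,
    min_prominence: float = 15.0,
    min_period: float = 0.6,
) -> list[GaitCycle]:
    """Delimit gait cycles on an anatomical knee flexion series.

    Peaks are local maxima with prominence >= ``min_prominence`` degrees
    separated by >= ``min_period`` seconds (conservative for healthy adult
    cadence; the early-stance flexion bump stays below the prominence
    floor). Raises NoCyclesError when fewer than two peaks qualify.
    """
    if series.convention != "anatomical":
        raise ValidationError("segment_cycles expects an anatomical-convention series")
    if series.joint != "knee":
        raise ValidationError("cycles are anchored on the knee flexion curve")
    n = len(series.values)
    if n < 2 * min_period * series.fps:
        raise NoCyclesError(
            f"series too short ({n} frames) to contain two periods of {min_period} s"
        )
    distance = max(1, int(round(min_period * series.fps)))
    peaks, _ = find_peaks(series.values, prominence=min_prominence, distance=distance)
    if len(peaks) < 2:
        raise NoCyclesError(
            f"found {len(peaks)} qualifying peak(s) "
            f"(prominence >= {min_prominence} deg); need at least 2"
        )
    return [
        GaitCycle(int(a), int(b), int(a)) for a, b in zip(peaks[:-1], peaks[1:])
    ]


def cycle_parameters(series: AngleSeries, cycle: GaitCycle) -> CycleParams:
    """Max/min/ROM of the angle over the cycle's frames [start, end)."""
    if cycle.end_frame > len(series.values):
        raise ValidationError(
            f"cycle [{cycle.start_frame}, {cycle.end_frame}) exceeds "
            f"series length {len(series.values)}"
        )
    window = series.values[cycle.start_frame : cycle.end_frame]
    if window.size == 0:
        raise ValidationError("cycle spans no frames")
    return CycleParams(float(window.max()), float(window.min()))


def session_summary(
    params: Sequence[CycleParams], *, joint: str, side: str
) -> SessionSummary:
    """Unweighted mean of each parameter across a session's cycles."""
    if len(params) == 0:
        raise ValidationError("session_summary requires at least one cycle")
    max_mean = float(np.mean([p.max_deg for p in params]))
    min_mean = float(np.mean([p.min_deg for p in params]))
    return SessionSummary(
        joint=joint,
        side=side,
        max_deg=max_mean,
        min_deg=min_mean,
        rom_deg=max_mean - min_mean,
        n_cycles=len(params),
        few_cycles=len(params) < 3,
    )


def subject_summary(sessions: Sequence[SessionSummary]) -> SubjectSummary:
    """Overall mean across sessions (the mean of mean1, mean2, ...)."""
    if len(sessions) == 0:
        raise ValidationError("subject_summary requires at least one session")
    joints = {(s.joint, s.side) for s in sessions}
    if len(joints) != 1:
        raise ValidationError(f"sessions mix joints/sides: {sorted(joints)}")
    max_mean = float(np.mean([s.max_deg for s in sessions]))
    min_mean = float(np.mean([s.min_deg for s in sessions]))
    return SubjectSummary(
        joint=sessions[0].joint,
        side=sessions[0].side,
        max_deg=max_mean,
        min_deg=min_mean,
        rom_deg=max_mean - min_mean,
        n_sessions=len(sessions),
    )


def parameter_rows(
    subject_id: str, summaries: Iterable[SubjectSummary | SessionSummary]
) -> pd.DataFrame:
    """Tidy (subject, joint, side, parameter, value_deg) rows.

    Knee: flexion_max = max angle, extension_min = min angle (residual
    flexion at the straightest point), rom. Ankle: dorsiflexion = max
    anatomical angle, plantarflexion = magnitude of the most negative
    angle, rom.
    """
    rows = []
    for s in summaries:
        if s.joint == "knee":
            triples = [
                ("flexion_max", s.max_deg),
                ("extension_min", s.min_deg),
                ("rom", s.rom_deg),
            ]
        else:
            triples = [
                ("dorsiflexion", s.max_deg),
                ("plantarflexion", -s.min_deg),
                ("rom", s.rom_deg),
            ]
        for name, value in triples:
            rows.append(
                {
                    "subject": subject_id,
                    "joint": s.joint,
                    "side": s.side,
                    "parameter": name,
                    "value_deg": value,
                }
            )
    return pd.DataFrame(rows, columns=["subject", "joint", "side", "parameter", "value_deg"])
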