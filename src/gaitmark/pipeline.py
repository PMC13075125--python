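"""End-to-end orchestration: landmarks -> angles -> cycles -> summaries.

One walking session is a landmark series; :func:`analyze_series` turns it
into four session summaries (knee/ankle x left/right) by optionally
undistorting, computing raw joint angles, converting to the anatomical
convention, segmenting gait cycles on the knee flexion curve, and
averaging the per-cycle parameters. :func:`analyze_subject` averages the
sessions of one subject into the overall per-subject summary table that
the agreement module consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .camera import CameraModel, undistort_series
from .cycles import (
    SessionSummary,
    cycle_parameters,
    parameter_rows,
    segment_cycles,
    session_summary,
    subject_summary,
)
from .errors import ValidationError
from .kinematics import joint_angle_series, smooth, to_anatomical
from .landmarks import LandmarkSeries, joint_spec_for

_SIDES = ("right", "left")


@dataclass(frozen=True)
class AnalysisSettings:
    """Tunables of the landmark-to-summary pipeline."""

    min_prominence: float = 15.0   # deg, knee-peak prominence floor
    min_period: float = 0.6        # s, minimum stride period
    smoothing_window: int | None = None  # odd frame count; None = no smoothing
    visibility_threshold: float = 0.5
    max_gap: int = 5               # frames of low visibility to interpolate


def analyze_series(
    series: LandmarkSeries,
    camera: CameraModel | None = None,
    settings: AnalysisSettings = AnalysisSettings(),
) -> list[SessionSummary]:
    """Session summaries (knee and ankle, both sides) for one walk."""
    work = series.to_pixels()
    if camera is not None and camera.has_distortion:
        work = undistort_series(camera, work)
    out: list[SessionSummary] = []
    for side in _SIDES:
        angle_series = {}
        for joint in ("knee", "ankle"):
            spec = joint_spec_for(joint, side, work.side_convention)
            raw = joint_angle_series(
                work,
                spec,
                visibility_threshold=settings.visibility_threshold,
                max_gap=settings.max_gap,
            )
            anat = to_anatomical(raw)
            if settings.smoothing_window is not None:
                anat = smooth(anat, settings.smoothing_window)
            angle_series[joint] = anat
        cycles = segment_cycles(
            angle_series["knee"], settings.min_prominence, settings.min_period
        )
        for joint in ("knee", "ankle"):
            params = [cycle_parameters(angle_series[joint], c) for c in cycles]
            out.append(session_summary(params, joint=joint, side=side))
    return out


def analyze_subject(
    subject_id: str,
    sessions: list[list[SessionSummary]],
) -> pd.DataFrame:
    """Average a subject's session summaries into tidy overall-mean rows."""
    if not sessions:
        raise ValidationError("analyze_subject requires at least one session")
    by_key: dict[tuple[str, str], list[SessionSummary]] = {}
    for sess in sessions:
        for s in sess:
            by_key.setdefault((s.joint, s.side), []).append(s)
    summaries = [subject_summary(v) for _k, v in sorted(by_key.items())]
    return parameter_rows(subject_id, summaries)


def analyze_sessions_frame(
    subject_sessions: dict[str, list[LandmarkSeries]],
    camera: CameraModel | None = None,
    settings: AnalysisSettings = AnalysisSettings(),
) -> pd.DataFrame:
    """Analyze many subjects' sessions into one tidy summary table."""
    frames = [
        analyze_subject(subject, [analyze_series(s, camera, settings) for s in series_list])
        for subject, series_list in sorted(subject_sessions.items())
    ]
    return pd.concat(frames, ignore_index=True)
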