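"""Per-frame sagittal joint angles from landmark triples.

The raw angle at a joint B defined by the triple (A, B, C) is

    theta = arccos( (B-A)·(C-B) / (|B-A| |C-B|) )   in [0, 180] degrees,

i.e. the turning angle between the proximal segment vector A->B and the
distal segment vector B->C. For the knee the triple is hip-knee-ankle and
theta is directly the flexion angle (0 = straight leg). For the ankle the
triple is knee-ankle-toe and the anatomical convention splits theta about
a neutral shank-foot configuration at theta = 90 degrees:

    anatomical ankle angle = 90 - theta   (positive = dorsiflexion,
                                           negative = plantarflexion).

The neutral offset cancels in any range-of-motion difference, so ROM is
identical in raw and anatomical form.

Angles are invariant under translation, rotation, reflection and uniform
scaling of the landmark coordinates — hence under the orthographic
world-to-pixel mapping, including the pixel y-axis flip.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, GapError, ValidationError
from .landmarks import JointSpec, LandmarkSeries


@dataclass
class AngleSeries:
    """Joint angle per frame, in degrees, for one joint/side."""

    joint: str
    side: str
    values: np.ndarray
    fps: float
    convention: str = "raw_theta"  # or "anatomical"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if self.convention not in ("raw_theta", "anatomical"):
            raise ValidationError(f"unknown convention {self.convention!r}")
        if self.convention == "raw_theta" and self.values.size:
            lo, hi = self.values.min(), self.values.max()
            if lo < -1e-9 or hi > 180 + 1e-9:
                raise ValidationError(
                    f"raw theta values must lie in [0, 180], got range [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        n = len(self.values)
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "timestamp": np.arange(n) / self.fps,
                "joint": self.joint,
                "side": self.side,
                "convention": self.convention,
                "value_deg": self.values,
            }
        )


def angle_between(a, b, c) -> float:
    """Turning angle at b for the triple (a, b, c), in degrees [0, 180].

    >>> angle_between((0, 0), (1, 0), (1, 1))
    90.0
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = b - a
    v = c - b
    nu = np.hypot(*u)
    nv = np.hypot(*v)
    if nu == 0.0:
        raise DegenerateGeometryError("zero-length segment between first and second point")
    if nv == 0.0:
        raise DegenerateGeometryError("zero-length segment between second and third point")
    cos = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def _segment_angles(A: np.ndarray, B: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Vectorized angle_between over (n, 2) arrays."""
    u = B - A
    v = C - B
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = np.nonzero((nu == 0) | (nv == 0))[0]
    if bad.size:
        raise DegenerateGeometryError(
            f"zero-length segment at frame(s) {bad[:5].tolist()}"
            + ("..." if bad.size > 5 else "")
        )
    cos = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    out = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _fill_gaps(track: np.ndarray, threshold: float, max_gap: int, landmark_id: int) -> np.ndarray:
    """Interpolate coordinates across short low-visibility runs.

    Interior runs are bridged linearly; runs touching the series edge are
    held at the nearest confident value. Any run longer than ``max_gap``
    frames raises GapError listing the frame range.
    """
    vis_ok = track[:, 2] >= threshold
    if vis_ok.all():
        return track[:, :2]
    if not vis_ok.any():
        raise GapError(f"landmark {landmark_id}: no frame reaches visibility {threshold}")
    long_runs = [(s, e) for s, e in _runs(~vis_ok) if e - s > max_gap]
    if long_runs:
        ranges = ", ".join(f"[{s}, {e})" for s, e in long_runs)
        raise GapError(
            f"landmark {landmark_id}: low-visibility run(s) longer than "
            f"{max_gap} frames at {ranges}"
        )
    idx = np.arange(len(track))
    good = idx[vis_ok]
    out = track[:, :2].copy()
    for col in (0, 1):
        out[:, col] = np.interp(idx, good, track[vis_ok, col])
    return out


def joint_angle_series(
    series: LandmarkSeries,
    spec: JointSpec,
    *,
    visibility_threshold: float = 0.5,
    max_gap: int = 5,
) -> AngleSeries:
    """Raw per-frame joint angle for the spec's landmark triple.

    Normalized-mode input is converted to pixels first (angle computation
    needs isotropic axes). Low-visibility landmarks are interpolated across
    gaps of at most ``max_gap`` frames; longer gaps raise GapError.
    """
    px = series.to_pixels()
    tracks = [
        _fill_gaps(px.landmark_track(lid), visibility_threshold, max_gap, lid)
        for lid in spec.landmark_ids
    ]
    values = _segment_angles(*tracks)
    return AngleSeries(spec.joint, spec.side, values, px.fps, "raw_theta")


def to_anatomical(series: AngleSeries) -> AngleSeries:
    """Convert raw theta to the anatomical convention.

    Knee: pass-through (theta already is the flexion angle). Ankle:
    ``90 - theta``, positive dorsiflexion, negative plantarflexion.
    """
    if series.convention != "raw_theta":
        raise ValidationError("series is already in anatomical convention")
    if series.joint == "knee":
        values = series.values.copy()
    else:
        values = 90.0 - series.values
    return replace(series, values=values, convention="anatomical")


def smooth(series: AngleSeries, window: int) -> AngleSeries:
    """Centered moving average with symmetrically shrunk edges.

    ``window`` must be odd; ``window=1`` is the identity. At index i the
    half-width shrinks to ``min(h, i, n-1-i)`` so the output stays within
    the input range and no phantom extrema appear. Off by default in the
    pipeline.
    """
    if window < 1 or window % 2 == 0:
        raise ValidationError(f"window must be an odd integer >= 1, got {window}")
    v = series.values
    n = len(v)
    h = window // 2
    if h == 0 or n == 0:
        return replace(series, values=v.copy())
    out = np.empty_like(v)
    csum = np.concatenate(([0.0], np.cumsum(v)))
    for i in range(n):
        hi = min(h, i, n - 1 - i)
        out[i] = (csum[i + hi + 1] - csum[i - hi]) / (2 * hi + 1)
    return replace(series, values=out)
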