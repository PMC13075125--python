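"""Radial lens-distortion model: apply and invert it on landmark coordinates.

A checkerboard calibration yields focal lengths, principal point and radial
distortion coefficients. Here the calibration itself is taken as given (the
model is an *input*); this module only applies the two-term radial model

    x_d = x_u * (1 + k1*r^2 + k2*r^4),   r^2 = x_u^2 + y_u^2

in normalized image coordinates, and inverts it by fixed-point iteration so
that landmark coordinates can be corrected before any angle is computed.
Tangential terms are deliberately omitted. Extrinsics may appear in a
config block and are stored but inert: summary-level sagittal angles need
no metric reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConvergenceError, ValidationError
from .landmarks import LandmarkFrame, LandmarkSeries

_MAX_ITER = 100
_TOL = 1e-9  # normalized units


@dataclass
class CameraModel:
    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    image_width: int = 1920
    image_height: int = 1080
    extrinsics: dict | None = field(default=None, repr=False)  # accepted, unused

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValidationError(f"focal lengths must be > 0, got fx={self.fx}, fy={self.fy}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValidationError("image dimensions must be positive")

    @property
    def has_distortion(self) -> bool:
        return self.k1 != 0.0 or self.k2 != 0.0

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        known = {k: d[k] for k in ("fx", "fy", "cx", "cy", "k1", "k2",
                                   "image_width", "image_height", "extrinsics") if k in d}
        missing = [k for k in ("fx", "fy", "cx", "cy") if k not in known]
        if missing:
            raise ValidationError(f"camera config missing field(s): {missing}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "CameraModel":
        doc = yaml.safe_load(Path(path).read_text())
        if not isinstance(doc, dict):
            raise ValidationError(f"camera config {path} is not a mapping")
        return cls.from_dict(doc.get("camera", doc))

    def to_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "k1": self.k1, "k2": self.k2,
            "image_width": self.image_width, "image_height": self.image_height,
        }


def _normalize(camera: CameraModel, pts: np.ndarray) -> np.ndarray:
    out = np.empty_like(pts)
    out[..., 0] = (pts[..., 0] - camera.cx) / camera.fx
    out[..., 1] = (pts[..., 1] - camera.cy) / camera.fy
    return out


def _denormalize(camera: CameraModel, pts: np.ndarray) -> np.ndarray:
    out = np.empty_like(pts)
    out[..., 0] = pts[..., 0] * camera.fx + camera.cx
    out[..., 1] = pts[..., 1] * camera.fy + camera.cy
    return out


def _radial_factor(camera: CameraModel, pts_n: np.ndarray) -> np.ndarray:
    r2 = pts_n[..., 0] ** 2 + pts_n[..., 1] ** 2
    return 1.0 + camera.k1 * r2 + camera.k2 * r2**2


def distort_points(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Apply the forward radial model to pixel points of shape (..., 2)."""
    points = np.asarray(points, dtype=float)
    if not camera.has_distortion:  # bit-exact identity
        return points.copy()
    pn = _normalize(camera, points)
    return _denormalize(camera, pn * _radial_factor(camera, pn)[..., None])


def undistort_points(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Invert the radial model by fixed-point iteration.

    Iterates ``x_u <- x_d / factor(x_u)`` from ``x_u = x_d`` until the
    update falls below 1e-9 normalized units; convergence holds for
    moderate distortion (|k1 r^2| well below 1). Raises ConvergenceError
    after 100 iterations.
    """
    points = np.asarray(points, dtype=float)
    if not camera.has_distortion:  # bit-exact identity
        return points.copy()
    pd_n = _normalize(camera, points)
    pu = pd_n.copy()
    for _ in range(_MAX_ITER):
        new = pd_n / _radial_factor(camera, pu)[..., None]
        step = np.max(np.abs(new - pu)) if new.size else 0.0
        pu = new
        if step < _TOL:
            return _denormalize(camera, pu)
    raise ConvergenceError(
        f"undistortion did not converge in {_MAX_ITER} iterations "
        f"(residual {step:.3g} normalized units); distortion too strong?"
    )


def distort_point(camera: CameraModel, point) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`distort_points`."""
    x, y = distort_points(camera, np.asarray(point, dtype=float))
    return float(x), float(y)


def undistort_point(camera: CameraModel, point) -> tuple[float, float]:
    """Scalar convenience wrapper around :func:`undistort_points`."""
    x, y = undistort_points(camera, np.asarray(point, dtype=float))
    return float(x), float(y)


def undistort_series(camera: CameraModel, series: LandmarkSeries) -> LandmarkSeries:
    """Undistort every landmark of a pixel-mode series.

    Visibility and timing are untouched. Normalized-mode input is refused:
    convert with ``series.to_pixels()`` first.
    """
    if series.coordinate_mode != "pixel":
        raise ValidationError(
            "undistort_series requires pixel coordinates; call series.to_pixels() first"
        )
    frames = []
    for f in series.frames:
        lids = sorted(f.landmarks)
        pts = np.array([f.landmarks[lid][:2] for lid in lids], dtype=float)
        und = undistort_points(camera, pts) if len(lids) else pts
        lms = {
            lid: (float(und[i, 0]), float(und[i, 1]), f.landmarks[lid][2])
            for i, lid in enumerate(lids)
        }
        frames.append(LandmarkFrame(f.frame_index, f.timestamp, lms))
    return LandmarkSeries(
        frames,
        fps=series.fps,
        coordinate_mode="pixel",
        image_width=series.image_width,
        image_height=series.image_height,
        side_convention=series.side_convention,
    )
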