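"""Pose-landmark time series: containers, topology, and file dialects.

The input to the pipeline is a time-ordered stream of 2D body landmarks in
the 33-point BlazePose topology, as emitted by a pose-estimation front end.
Only the eight lower-limb landmarks (hips, knees, ankles, toes) are needed
for sagittal knee/ankle kinematics, but any subset of ids 0-32 is accepted
and preserved.

Two on-disk dialects are supported:

``csv``
    Long format, one row per landmark per frame with columns
    ``frame,timestamp,landmark_id,x,y,visibility`` plus a JSON metadata
    sidecar ``<path>.meta.json`` holding fps, coordinate mode, image size
    and side convention. Diff-able and stream-friendly.
``json``
    A single self-describing document with the same information.

Side conventions
----------------
The published BlazePose topology assigns index 23 to the *left* hip. Some
processing chains instead treat 23 as the *right* hip (a lateral-view
mirror). Both mappings are first-class here: ``side_convention="official"``
follows the published topology, ``side_convention="paper"`` the mirrored
one. The default is "paper"; nothing is silently corrected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import OrderingError, SchemaError, ValidationError

N_LANDMARKS = 33

_PAPER_IDS: dict[tuple[str, str], int] = {
    ("hip", "right"): 23, ("hip", "left"): 24,
    ("knee", "right"): 25, ("knee", "left"): 26,
    ("ankle", "right"): 27, ("ankle", "left"): 28,
    ("toe", "right"): 31, ("toe", "left"): 32,
}
_MIRROR = {"right": "left", "left": "right"}
_OFFICIAL_IDS = {(role, _MIRROR[side]): lid for (role, side), lid in _PAPER_IDS.items()}
CONVENTIONS = {"paper": _PAPER_IDS, "official": _OFFICIAL_IDS}

#: landmark ids a JointSpec may draw from
_JOINT_ID_POOL = frozenset(_PAPER_IDS.values())

_CSV_COLUMNS = ["frame", "timestamp", "landmark_id", "x", "y", "visibility"]


@dataclass(frozen=True)
class JointSpec:
    """Ordered landmark triple defining one sagittal joint angle.

    For the knee the triple is (hip, knee, ankle); for the ankle it is
    (knee, ankle, toe). The angle is measured between the two segment
    vectors first->second and second->third.
    """

    joint: str
    side: str
    landmark_ids: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.joint not in ("knee", "ankle"):
            raise ValidationError(f"joint must be 'knee' or 'ankle', got {self.joint!r}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"side must be 'left' or 'right', got {self.side!r}")
        ids = tuple(self.landmark_ids)
        if len(ids) != 3 or len(set(ids)) != 3:
            raise ValidationError(f"landmark_ids must be three distinct ids, got {ids}")
        bad = [i for i in ids if i not in _JOINT_ID_POOL]
        if bad:
            raise ValidationError(
                f"landmark_ids must be lower-limb ids {sorted(_JOINT_ID_POOL)}, got {bad}"
            )


def joint_spec_for(joint: str, side: str, side_convention: str = "paper") -> JointSpec:
    """Return the landmark triple for a joint/side under a convention.

    >>> joint_spec_for("knee", "right", "paper").landmark_ids
    (23, 25, 27)
    """
    try:
        table = CONVENTIONS[side_convention]
    except KeyError:
        raise ValidationError(
            f"unknown side_convention {side_convention!r}; expected 'paper' or 'official'"
        ) from None
    if joint == "knee":
        roles = ("hip", "knee", "ankle")
    elif joint == "ankle":
        roles = ("knee", "ankle", "toe")
    else:
        raise ValidationError(f"joint must be 'knee' or 'ankle', got {joint!r}")
    if side not in ("left", "right"):
        raise ValidationError(f"side must be 'left' or 'right', got {side!r}")
    return JointSpec(joint, side, tuple(table[(role, side)] for role in roles))


@dataclass
class LandmarkFrame:
    """All landmarks observed in one video frame.

    ``landmarks`` maps landmark_id (0-32) to ``(x, y, visibility)``;
    coordinates are pixels or normalized units depending on the series,
    visibility lies in [0, 1].
    """

    frame_index: int
    timestamp: float
    landmarks: dict[int, tuple[float, float, float]]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValidationError(f"frame_index must be >= 0, got {self.frame_index}")
        for lid, (x, y, v) in self.landmarks.items():
            if not (0 <= lid < N_LANDMARKS):
                raise SchemaError(f"landmark_id {lid} outside 0-{N_LANDMARKS - 1}")
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValidationError(f"non-finite coordinate for landmark {lid}")
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"visibility {v} for landmark {lid} outside [0, 1]")


@dataclass
class LandmarkSeries:
    """A time-ordered landmark stream with acquisition metadata."""

    frames: list[LandmarkFrame]
    fps: float
    coordinate_mode: str = "pixel"
    image_width: int = 1920
    image_height: int = 1080
    side_convention: str = "paper"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValidationError(f"fps must be > 0, got {self.fps}")
        if self.coordinate_mode not in ("pixel", "normalized"):
            raise ValidationError(
                f"coordinate_mode must be 'pixel' or 'normalized', got {self.coordinate_mode!r}"
            )
        if self.side_convention not in CONVENTIONS:
            raise ValidationError(f"unknown side_convention {self.side_convention!r}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValidationError("image dimensions must be positive")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise OrderingError("frame_index must be strictly increasing")
        if self.coordinate_mode == "normalized":
            for f in self.frames:
                for lid, (x, y, _v) in f.landmarks.items():
                    if not (-1e-9 <= x <= 1 + 1e-9 and -1e-9 <= y <= 1 + 1e-9):
                        raise ValidationError(
                            f"normalized coordinate outside [0, 1] at frame "
                            f"{f.frame_index}, landmark {lid}"
                        )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([f.timestamp for f in self.frames], dtype=float)

    def landmark_track(self, landmark_id: int) -> np.ndarray:
        """(n_frames, 3) array of x, y, visibility for one landmark.

        Raises SchemaError if the landmark is absent from any frame.
        """
        out = np.empty((len(self.frames), 3), dtype=float)
        missing = []
        for i, f in enumerate(self.frames):
            rec = f.landmarks.get(landmark_id)
            if rec is None:
                missing.append(f.frame_index)
            else:
                out[i] = rec
        if missing:
            raise SchemaError(
                f"landmark {landmark_id} missing in {len(missing)} frame(s), "
                f"first at frame {missing[0]}"
            )
        return out

    def to_pixels(self) -> "LandmarkSeries":
        """Return a pixel-mode copy (identity if already pixel mode).

        Normalized x is scaled by image_width and y by image_height, which
        restores the isotropic geometry angle computations require.
        """
        if self.coordinate_mode == "pixel":
            return self
        w, h = self.image_width, self.image_height
        frames = [
            LandmarkFrame(
                f.frame_index,
                f.timestamp,
                {lid: (x * w, y * h, v) for lid, (x, y, v) in f.landmarks.items()},
            )
            for f in self.frames
        ]
        return replace(self, frames=frames, coordinate_mode="pixel")

    @classmethod
    def from_arrays(
        cls,
        coords: Mapping[int, np.ndarray],
        visibility: Mapping[int, np.ndarray],
        fps: float,
        **meta,
    ) -> "LandmarkSeries":
        """Build a series from per-landmark ``(n, 2)`` coordinate arrays."""
        n = {len(a) for a in coords.values()}
        if len(n) != 1:
            raise ValidationError("all landmark tracks must have equal length")
        n = n.pop()
        frames = []
        for i in range(n):
            lms = {
                lid: (float(xy[i, 0]), float(xy[i, 1]), float(visibility[lid][i]))
                for lid, xy in coords.items()
            }
            frames.append(LandmarkFrame(i, i / fps, lms))
        return cls(frames, fps=fps, **meta)


def _infer_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "json"):
            raise ValidationError(f"unknown dialect {dialect!r}")
        return dialect
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".json":
        return "json"
    raise ValidationError(f"cannot infer dialect from suffix {suffix!r}; pass dialect=")


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _meta_dict(series: LandmarkSeries) -> dict:
    return {
        "fps": series.fps,
        "coordinate_mode": series.coordinate_mode,
        "image_width": series.image_width,
        "image_height": series.image_height,
        "side_convention": series.side_convention,
    }


def write_landmark_series(series: LandmarkSeries, path, dialect: str | None = None) -> None:
    """Write a series in the csv or json dialect (inferred from suffix)."""
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        rows = [
            (f.frame_index, f.timestamp, lid, x, y, v)
            for f in series.frames
            for lid, (x, y, v) in sorted(f.landmarks.items())
        ]
        df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
        df.to_csv(path, index=False, float_format="%.10g")
        _meta_path(path).write_text(json.dumps(_meta_dict(series), indent=1))
    else:
        doc = dict(_meta_dict(series))
        doc["frames"] = [
            {
                "frame_index": f.frame_index,
                "timestamp": f.timestamp,
                "landmarks": {str(lid): list(rec) for lid, rec in sorted(f.landmarks.items())},
            }
            for f in series.frames
        ]
        Path(path).write_text(json.dumps(doc))


def read_landmark_series(path, dialect: str | None = None) -> LandmarkSeries:
    """Read a series written by :func:`write_landmark_series`.

    Schema violations raise SchemaError naming the offending columns or
    landmark ids; non-monotone frame indices raise OrderingError. A missing
    or NaN timestamp is derived as ``frame / fps``.
    """
    path = Path(path)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        meta_path = _meta_path(path)
        if not meta_path.exists():
            raise SchemaError(f"missing metadata sidecar {meta_path}")
        meta = json.loads(meta_path.read_text())
        df = pd.read_csv(path)
        missing = [c for c in _CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"landmark CSV missing required column(s): {missing}")
        frames: list[LandmarkFrame] = []
        fps = float(meta["fps"])
        for frame_idx, grp in df.groupby("frame", sort=False):
            ts = grp["timestamp"].iloc[0]
            if pd.isna(ts):
                ts = float(frame_idx) / fps
            lms = {
                int(r.landmark_id): (float(r.x), float(r.y), float(r.visibility))
                for r in grp.itertuples()
            }
            frames.append(LandmarkFrame(int(frame_idx), float(ts), lms))
        return LandmarkSeries(
            frames,
            fps=fps,
            coordinate_mode=meta["coordinate_mode"],
            image_width=int(meta["image_width"]),
            image_height=int(meta["image_height"]),
            side_convention=meta["side_convention"],
        )
    doc = json.loads(Path(path).read_text())
    required = {"fps", "coordinate_mode", "image_width", "image_height",
                "side_convention", "frames"}
    missing = sorted(required - doc.keys())
    if missing:
        raise SchemaError(f"landmark JSON missing required field(s): {missing}")
    frames = [
        LandmarkFrame(
            int(f["frame_index"]),
            float(f["timestamp"]),
            {int(lid): tuple(map(float, rec)) for lid, rec in f["landmarks"].items()},
        )
        for f in doc["frames"]
    ]
    return LandmarkSeries(
        frames,
        fps=float(doc["fps"]),
        coordinate_mode=doc["coordinate_mode"],
        image_width=int(doc["image_width"]),
        image_height=int(doc["image_height"]),
        side_convention=doc["side_convention"],
    )
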