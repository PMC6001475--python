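"""Moving eyes/mouth areas of interest (AOIs) anchored to facial landmarks.

The talker's face is covered by two equal semicircular AOIs whose shared
flat edge crosses the nose: the diameter line is perpendicular to the
eyes--mouth axis and passes through the midpoint of the two landmark
centres, so the edge stays equidistant from eyes and mouth as the face
moves.  Gaze points are classified into ``EYES`` (the half-disk containing
the eyes centre), ``MOUTH`` (the half-disk containing the mouth centre) or
``NEITHER`` (outside the disk).

Coordinates are screen pixels with the origin at the top-left corner and y
increasing downward, the usual remote-eye-tracker export convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AOILabel",
    "Point",
    "FaceLandmarks",
    "AOIPair",
    "LandmarkTrack",
    "DegenerateGeometryError",
    "MissingTrackError",
    "build_aoi_pair",
    "classify_point",
    "classify_points",
    "CODE_EYES",
    "CODE_MOUTH",
    "CODE_NEITHER",
    "landmarks_at",
    "read_landmark_tracks",
    "write_landmark_tracks",
]

#: Dot products whose magnitude falls below this are treated as lying on the
#: dividing line and labelled MOUTH (fixed, measure-zero tie-break).
DIVIDING_LINE_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Eyes and mouth landmarks coincide; no AOI pair can be constructed."""


class MissingTrackError(ValueError):
    """A landmark track was empty or absent for the requested trial."""


class AOILabel(Enum):
    EYES = "eyes"
    MOUTH = "mouth"
    NEITHER = "neither"


# integer codes used by the vectorised classifier
CODE_EYES, CODE_MOUTH, CODE_NEITHER = 0, 1, 2
CODE_TO_LABEL = {CODE_EYES: AOILabel.EYES, CODE_MOUTH: AOILabel.MOUTH,
                 CODE_NEITHER: AOILabel.NEITHER}


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")


@dataclass(frozen=True)
class FaceLandmarks:
    """Eyes-centre and mouth-centre of the talker at one video time point."""

    t: float
    eyes_centre: Point
    mouth_centre: Point

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"landmark time must be >= 0, got {self.t}")
        if (self.eyes_centre.x == self.mouth_centre.x
                and self.eyes_centre.y == self.mouth_centre.y):
            raise DegenerateGeometryError(
                "eyes and mouth landmarks coincide at "
                f"({self.eyes_centre.x}, {self.eyes_centre.y})")


@dataclass(frozen=True)
class AOIPair:
    """Two disjoint semicircular AOIs partitioning a disk about ``centre``.

    ``axis`` is the unit vector from the mouth centre toward the eyes
    centre; the dividing diameter is perpendicular to it.
    """

    centre: Point
    axis: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        norm = math.hypot(*self.axis)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError(f"axis must be a unit vector, |axis| = {norm}")
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


def build_aoi_pair(landmarks: FaceLandmarks, radius_factor: float = 2.0) -> AOIPair:
    """Construct the semicircular AOI pair for one landmark configuration.

    The disk is centred on the midpoint of the eyes and mouth centres with
    radius ``radius_factor`` times half the eyes--mouth distance, so with
    ``radius_factor > 1`` each landmark lies strictly inside its own
    half-disk.
    """
    if radius_factor <= 1:
        raise ValueError(f"radius_factor must exceed 1, got {radius_factor}")
    e, m = landmarks.eyes_centre, landmarks.mouth_centre
    dx, dy = e.x - m.x, e.y - m.y
    dist = math.hypot(dx, dy)
    if dist == 0.0:  # unreachable through FaceLandmarks, kept for raw use
        raise DegenerateGeometryError("coincident landmarks")
    centre = Point((e.x + m.x) / 2.0, (e.y + m.y) / 2.0)
    return AOIPair(centre=centre, axis=(dx / dist, dy / dist),
                   radius=radius_factor * dist / 2.0)


def classify_point(aoi: AOIPair, p: Point) -> AOILabel:
    """Label a gaze point against an AOI pair.

    Points outside the disk are NEITHER; inside, the sign of the projection
    onto the mouth-to-eyes axis decides, with the dividing line itself
    (projection zero within tolerance) labelled MOUTH.
    """
    rx, ry = p.x - aoi.centre.x, p.y - aoi.centre.y
    if math.hypot(rx, ry) > aoi.radius:
        return AOILabel.NEITHER
    dot = rx * aoi.axis[0] + ry * aoi.axis[1]
    return AOILabel.EYES if dot > DIVIDING_LINE_TOL else AOILabel.MOUTH


def classify_points(
    eyes_xy: np.ndarray,
    mouth_xy: np.ndarray,
    points_xy: np.ndarray,
    radius_factor: float = 2.0,
) -> np.ndarray:
    """Vectorised classification of gaze points against per-sample AOIs.

    Parameters
    ----------
    eyes_xy, mouth_xy : (n, 2) arrays
        Landmark centres evaluated at each sample's timestamp.
    points_xy : (n, 2) array
        Gaze positions.

    Returns
    -------
    (n,) int array of codes: 0 = EYES, 1 = MOUTH, 2 = NEITHER.
    """
    eyes_xy = np.asarray(eyes_xy, dtype=float)
    mouth_xy = np.asarray(mouth_xy, dtype=float)
    points_xy = np.asarray(points_xy, dtype=float)
    d = eyes_xy - mouth_xy
    dist = np.hypot(d[:, 0], d[:, 1])
    if np.any(dist == 0.0):
        raise DegenerateGeometryError("coincident landmarks in track")
    centre = (eyes_xy + mouth_xy) / 2.0
    radius = radius_factor * dist / 2.0
    axis = d / dist[:, None]
    rel = points_xy - centre
    inside = np.hypot(rel[:, 0], rel[:, 1]) <= radius
    dot = rel[:, 0] * axis[:, 0] + rel[:, 1] * axis[:, 1]
    codes = np.full(len(points_xy), CODE_NEITHER, dtype=np.int8)
    codes[inside & (dot > DIVIDING_LINE_TOL)] = CODE_EYES
    codes[inside & (dot <= DIVIDING_LINE_TOL)] = CODE_MOUTH
    return codes


class LandmarkTrack:
    """Time-ordered facial landmark keyframes for one stimulus video.

    Landmark positions between keyframes are linearly interpolated; queries
    outside the keyframed range clamp to the first/last entry.
    """

    def __init__(self, t: Sequence[float], eyes_xy: np.ndarray, mouth_xy: np.ndarray):
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            raise MissingTrackError("empty landmark track")
        if np.any(np.diff(t) <= 0):
            raise ValueError("landmark keyframes must be strictly increasing in t")
        self.t = t
        self.eyes_xy = np.asarray(eyes_xy, dtype=float).reshape(-1, 2)
        self.mouth_xy = np.asarray(mouth_xy, dtype=float).reshape(-1, 2)
        if not (len(self.t) == len(self.eyes_xy) == len(self.mouth_xy)):
            raise ValueError("track arrays must have equal length")

    @classmethod
    def from_landmarks(cls, entries: Iterable[FaceLandmarks]) -> "LandmarkTrack":
        entries = list(entries)
        if not entries:
            raise MissingTrackError("empty landmark track")
        return cls(
            [lm.t for lm in entries],
            np.array([[lm.eyes_centre.x, lm.eyes_centre.y] for lm in entries]),
            np.array([[lm.mouth_centre.x, lm.mouth_centre.y] for lm in entries]),
        )

    def __len__(self) -> int:
        return len(self.t)

    def interpolate(self, ts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Landmark positions at arbitrary times (clamped linear interpolation)."""
        ts = np.asarray(ts, dtype=float)
        eyes = np.column_stack([np.interp(ts, self.t, self.eyes_xy[:, i]) for i in (0, 1)])
        mouth = np.column_stack([np.interp(ts, self.t, self.mouth_xy[:, i]) for i in (0, 1)])
        return eyes, mouth

    def to_frame(self, trial_id) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_id": trial_id,
            "t_ms": self.t,
            "eyes_x": self.eyes_xy[:, 0], "eyes_y": self.eyes_xy[:, 1],
            "mouth_x": self.mouth_xy[:, 0], "mouth_y": self.mouth_xy[:, 1],
        })


def landmarks_at(track: LandmarkTrack | Sequence[FaceLandmarks], t: float) -> FaceLandmarks:
    """Landmark configuration at time ``t`` (ms from video start)."""
    if not isinstance(track, LandmarkTrack):
        track = LandmarkTrack.from_landmarks(track)
    eyes, mouth = track.interpolate(np.array([t]))
    return FaceLandmarks(
        t=max(float(t), 0.0),
        eyes_centre=Point(float(eyes[0, 0]), float(eyes[0, 1])),
        mouth_centre=Point(float(mouth[0, 0]), float(mouth[0, 1])),
    )


_TRACK_COLUMNS = ["trial_id", "t_ms", "eyes_x", "eyes_y", "mouth_x", "mouth_y"]


def read_landmark_tracks(source: str | Path) -> dict:
    """Read a landmark-track CSV (one keyframe per row) into per-trial tracks."""
    df = pd.read_csv(source)
    missing = set(_TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark track file missing columns: {sorted(missing)}")
    tracks = {}
    for trial_id, g in df.groupby("trial_id", sort=True):
        g = g.sort_values("t_ms")
        tracks[trial_id] = LandmarkTrack(
            g["t_ms"].to_numpy(),
            g[["eyes_x", "eyes_y"]].to_numpy(),
            g[["mouth_x", "mouth_y"]].to_numpy(),
        )
    return tracks


def write_landmark_tracks(tracks: Mapping, dest: str | Path) -> None:
    frames = [trk.to_frame(trial_id) for trial_id, trk in sorted(tracks.items())]
    pd.concat(frames, ignore_index=True).to_csv(dest, index=False, float_format="%.6g")
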