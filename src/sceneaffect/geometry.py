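"""Polyline contour geometry.

A *contour* is an ordered polyline of fiducial points on a pixel canvas
(image convention: origin top-left, x rightward, y downward).  All other
modules build on the five quantities defined here: per-segment lengths and
orientations, total contour length, per-vertex angularity (turn angle per
pixel), and the folded mean orientation used for contour-level
classification.

Orientations are reported in *visual* space: because the canvas y axis
points down, the counter-clockwise angle from horizontal is computed from
(dx, -dy) and reduced modulo 180 degrees, so a segment that visually rises
to the right has orientation 45 even though its canvas dy is negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Contour",
    "LineDrawing",
    "InvalidContourError",
    "segment_lengths",
    "segment_orientations",
    "contour_length",
    "vertex_angularities",
    "folded_mean_orientation",
    "fold_orientation",
]


class InvalidContourError(ValueError):
    """Raised when a polyline violates the contour invariants."""


def _as_points(points: Iterable[Sequence[float]] | np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidContourError(
            f"points must be an (n, 2) array of coordinates, got shape {pts.shape}"
        )
    return pts


@dataclass(frozen=True)
class Contour:
    """An ordered open polyline of fiducial points.

    Parameters
    ----------
    points : (n, 2) array-like
        Vertex coordinates in pixels, n >= 2.  Consecutive points must be
        distinct so every segment has positive length.
    id : str
        Opaque identifier used for provenance tracking.
    """

    points: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        pts = _as_points(self.points)
        if len(pts) < 2:
            raise InvalidContourError(
                f"contour {self.id!r} needs at least 2 points, got {len(pts)}"
            )
        if not np.all(np.isfinite(pts)):
            raise InvalidContourError(f"contour {self.id!r} has non-finite coordinates")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise InvalidContourError(
                f"contour {self.id!r} has repeated consecutive points"
            )
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_segments(self) -> int:
        return len(self.points) - 1

    def translated(self, dx: float, dy: float) -> "Contour":
        return Contour(self.points + [dx, dy], id=self.id)

    def reversed(self) -> "Contour":
        return Contour(self.points[::-1], id=self.id)

    def scaled(self, s: float) -> "Contour":
        return Contour(self.points * s, id=self.id)


@dataclass(frozen=True)
class LineDrawing:
    """A set of contours on a rectangular pixel canvas."""

    contours: tuple[Contour, ...]
    canvas_width: float
    canvas_height: float

    def __post_init__(self) -> None:
        contours = tuple(self.contours)
        if not contours:
            raise InvalidContourError("a line drawing needs at least one contour")
        for c in contours:
            x, y = c.points[:, 0], c.points[:, 1]
            if (
                x.min() < -1e-9
                or y.min() < -1e-9
                or x.max() > self.canvas_width + 1e-9
                or y.max() > self.canvas_height + 1e-9
            ):
                raise InvalidContourError(
                    f"contour {c.id!r} exceeds the "
                    f"{self.canvas_width}x{self.canvas_height} canvas "
                    f"(bbox x [{x.min():g}, {x.max():g}], y [{y.min():g}, {y.max():g}])"
                )
        object.__setattr__(self, "contours", contours)

    @property
    def n_contours(self) -> int:
        return len(self.contours)

    def total_length(self) -> float:
        return float(sum(contour_length(c) for c in self.contours))


def _segments(contour: Contour) -> np.ndarray:
    return np.diff(contour.points, axis=0)


def segment_lengths(contour: Contour) -> np.ndarray:
    """Euclidean length of each segment, in pixels (all > 0)."""
    seg = _segments(contour)
    return np.hypot(seg[:, 0], seg[:, 1])


def segment_orientations(contour: Contour) -> np.ndarray:
    """Orientation of each segment in degrees, in [0, 180).

    The counter-clockwise angle from horizontal in visual space; reversing
    the contour leaves the values unchanged.
    """
    seg = _segments(contour)
    ang = np.degrees(np.arctan2(-seg[:, 1], seg[:, 0])) % 180.0
    # floating-point wrap: 179.9999999.. from a nominally horizontal segment
    ang[np.isclose(ang, 180.0)] = 0.0
    return ang


def contour_length(contour: Contour) -> float:
    """Total pixel length of the contour (sum of its segment lengths)."""
    return float(segment_lengths(contour).sum())


def vertex_angularities(
    contour: Contour,
    denominator: Literal["mean", "min", "sum"] = "mean",
) -> np.ndarray:
    """Turn angle per pixel at each interior vertex, in degrees/pixel.

    At each interior vertex the absolute turn angle between the incoming and
    outgoing segment directions (in [0, 180]) is divided by a length scale
    formed from the two adjacent segment lengths: their mean (default),
    minimum, or sum.  A 2-point contour has no interior vertex and yields an
    empty array; collinear vertices yield 0.
    """
    seg = _segments(contour)
    lens = np.hypot(seg[:, 0], seg[:, 1])
    if len(seg) < 2:
        return np.empty(0)
    u, v = seg[:-1], seg[1:]
    cosang = (u * v).sum(axis=1) / (lens[:-1] * lens[1:])
    turn = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if denominator == "mean":
        scale = 0.5 * (lens[:-1] + lens[1:])
    elif denominator == "min":
        scale = np.minimum(lens[:-1], lens[1:])
    elif denominator == "sum":
        scale = lens[:-1] + lens[1:]
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown angularity denominator {denominator!r}")
    return turn / scale


def fold_orientation(theta: np.ndarray | float) -> np.ndarray | float:
    """Fold orientations from [0, 180) onto [0, 90] (180 == 0)."""
    theta = np.asarray(theta, dtype=float)
    folded = np.where(theta > 90.0, 180.0 - theta, theta)
    return folded if folded.ndim else float(folded)


def folded_mean_orientation(contour: Contour, weighted: bool = True) -> float:
    """Mean folded segment orientation of a contour, in [0, 90] degrees.

    Each segment orientation is folded onto [0, 90] and averaged, by default
    weighting each segment by its pixel length (set ``weighted=False`` for
    the unweighted mean over segments).
    """
    folded = np.asarray(fold_orientation(segment_orientations(contour)))
    if weighted:
        w = segment_lengths(contour)
        return float(np.average(folded, weights=w))
    return float(folded.mean())
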