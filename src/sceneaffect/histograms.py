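"""Eight-bin contour-feature histograms and the regression feature vector.

Each line drawing is summarised by three pixel-weighted histograms:

* **orientation** — every segment contributes its pixel length at its
  orientation, split between the two circularly adjacent bin centers
  (spaced 22.5 degrees apart, so 157.5 wraps towards 0);
* **length** — every contour contributes its total pixel length at the
  log10 of that length, between log-spaced bin centers;
* **angularity** — every interior vertex contributes the two half-segments
  adjacent to it (half of each neighbouring segment, so mass is conserved)
  at the log10 of its turn-angle-per-pixel; the half-segments at contour
  endpoints, and entire 2-point contours, carry no turn and fall in the
  lowest bin.

The total mass of each histogram equals the drawing's total contour length
in pixels.  The regression feature vector concatenates the three histograms,
drops the top length bin (too rare to estimate), and optionally applies an
element-wise square root, giving 23 predictors:
Orientation 1-8, Length 1-7, Angularity 1-8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import (
    LineDrawing,
    contour_length,
    segment_lengths,
    segment_orientations,
    vertex_angularities,
)

__all__ = [
    "BinSpec",
    "FeatureHistogram",
    "FeatureVector",
    "FEATURE_NAMES",
    "orientation_histogram",
    "length_histogram",
    "angularity_histogram",
    "feature_vector",
    "feature_table",
    "ContourFeatureExtractor",
]

BinningMode = Literal["triangular", "nearest"]

#: Predictor names of the 23-dimensional feature vector, in order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"O{i}" for i in range(1, 9)]
    + [f"L{i}" for i in range(1, 8)]
    + [f"A{i}" for i in range(1, 9)]
)


@dataclass(frozen=True)
class BinSpec:
    """Bin centers of the three 8-bin feature histograms.

    Orientation centers are evenly spaced degrees; length (pixels) and
    angularity (degrees/pixel) centers are evenly spaced in log10, taken as
    fixed constants of the method.
    """

    orientation_centers: tuple[float, ...] = (
        0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5,
    )
    length_centers: tuple[float, ...] = (
        1.66, 4.47, 12.02, 32.36, 87.10, 232.42, 630.96, 1698.24,
    )
    angularity_centers: tuple[float, ...] = (
        1.38, 2.63, 5.13, 9.77, 18.62, 35.48, 67.61, 131.83,
    )

    def __post_init__(self) -> None:
        for name in ("orientation_centers", "length_centers", "angularity_centers"):
            centers = np.asarray(getattr(self, name), dtype=float)
            if centers.shape != (8,):
                raise ValueError(f"{name} must have exactly 8 entries")
            if np.any(np.diff(centers) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass(frozen=True)
class FeatureHistogram:
    """An 8-bin pixel-weighted histogram of one contour feature."""

    feature_name: Literal["orientation", "length", "angularity"]
    bin_centers: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if centers.shape != (8,) or weights.shape != (8,):
            raise ValueError("a feature histogram has exactly 8 bins")
        if np.any(weights < -1e-9):
            raise ValueError("histogram weights must be non-negative")
        centers.setflags(write=False)
        weights.setflags(write=False)
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "weights", weights)

    @property
    def total_mass(self) -> float:
        return float(self.weights.sum())


@dataclass(frozen=True)
class FeatureVector:
    """The 23-entry regression predictor vector of one drawing."""

    values: np.ndarray
    sqrt_applied: bool
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (23,):
            raise ValueError(f"feature vector must have 23 entries, got {values.shape}")
        if np.any(values < -1e-9):
            raise ValueError("feature vector entries must be non-negative")
        values.setflags(write=False)
        object.__setattr__(self, "values", values)


def _triangular_weights(
    positions: np.ndarray, centers: np.ndarray, circular_period: float | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split unit mass at each position between its two bracketing centers.

    Returns (lower bin index, upper bin index, fraction assigned to upper).
    Non-circular axes clamp positions beyond the extreme centers onto the
    end bins.
    """
    k = len(centers)
    if circular_period is not None:
        pos = positions % circular_period
        step = circular_period / k
        lo = np.floor(pos / step).astype(int)
        frac = pos / step - lo
        return lo % k, (lo + 1) % k, frac
    pos = np.clip(positions, centers[0], centers[-1])
    lo = np.clip(np.searchsorted(centers, pos, side="right") - 1, 0, k - 2)
    gap = centers[lo + 1] - centers[lo]
    frac = (pos - centers[lo]) / gap
    return lo, lo + 1, frac


def _bin_mass(
    positions: np.ndarray,
    masses: np.ndarray,
    centers: np.ndarray,
    mode: BinningMode,
    circular_period: float | None = None,
) -> np.ndarray:
    weights = np.zeros(len(centers))
    if len(positions) == 0:
        return weights
    lo, hi, frac = _triangular_weights(np.asarray(positions, float), centers, circular_period)
    if mode == "nearest":
        hard = np.where(frac > 0.5, hi, lo)
        np.add.at(weights, hard, masses)
    elif mode == "triangular":
        np.add.at(weights, lo, masses * (1.0 - frac))
        np.add.at(weights, hi, masses * frac)
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return weights


def orientation_histogram(
    drawing: LineDrawing,
    spec: BinSpec | None = None,
    mode: BinningMode = "triangular",
) -> FeatureHistogram:
    """Pixel-length-weighted histogram of segment orientations."""
    spec = spec or BinSpec()
    centers = np.asarray(spec.orientation_centers)
    weights = np.zeros(8)
    for c in drawing.contours:
        weights += _bin_mass(
            segment_orientations(c), segment_lengths(c), centers, mode,
            circular_period=180.0,
        )
    return FeatureHistogram("orientation", centers, weights)


def length_histogram(
    drawing: LineDrawing,
    spec: BinSpec | None = None,
    mode: BinningMode = "triangular",
) -> FeatureHistogram:
    """Per-contour pixel mass binned by log10 contour length."""
    spec = spec or BinSpec()
    centers = np.asarray(spec.length_centers)
    lengths = np.array([contour_length(c) for c in drawing.contours])
    weights = _bin_mass(np.log10(lengths), lengths, np.log10(centers), mode)
    return FeatureHistogram("length", centers, weights)


def angularity_histogram(
    drawing: LineDrawing,
    spec: BinSpec | None = None,
    mode: BinningMode = "triangular",
    denominator: Literal["mean", "min", "sum"] = "mean",
) -> FeatureHistogram:
    """Half-segment pixel mass binned by log10 vertex angularity.

    Mass without an interior vertex (endpoint half-segments, whole 2-point
    contours) and vertices below the lowest center fall in bin 1, the
    zero-turn class, which keeps the histogram mass equal to the drawing's
    total contour length.
    """
    spec = spec or BinSpec()
    centers = np.asarray(spec.angularity_centers)
    log_centers = np.log10(centers)
    weights = np.zeros(8)
    for c in drawing.contours:
        lens = segment_lengths(c)
        ang = vertex_angularities(c, denominator=denominator)
        # endpoint halves: first half of first segment + last half of last
        weights[0] += 0.5 * (lens[0] + lens[-1])
        if len(ang) == 0:
            continue
        vertex_mass = 0.5 * (lens[:-1] + lens[1:])
        positive = ang > 0
        weights[0] += vertex_mass[~positive].sum()  # zero turns: log undefined
        weights += _bin_mass(
            np.log10(ang[positive]), vertex_mass[positive], log_centers, mode
        )
    return FeatureHistogram("angularity", centers, weights)


def feature_vector(
    drawing: LineDrawing,
    spec: BinSpec | None = None,
    apply_sqrt: bool = True,
    mode: BinningMode = "triangular",
) -> FeatureVector:
    """The 23-entry predictor vector: O1-8, L1-7 (L8 dropped), A1-8."""
    spec = spec or BinSpec()
    o = orientation_histogram(drawing, spec, mode).weights
    l = length_histogram(drawing, spec, mode).weights[:7]
    a = angularity_histogram(drawing, spec, mode).weights
    values = np.concatenate([o, l, a])
    if apply_sqrt:
        values = np.sqrt(values)
    return FeatureVector(values, sqrt_applied=apply_sqrt)


class ContourFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform line drawings into the 23-column feature matrix.

    A stateless scikit-learn transformer: ``transform`` maps a sequence of
    :class:`~sceneaffect.geometry.LineDrawing` objects to an ``(n, 23)``
    array of (optionally square-root transformed) histogram features.

    Parameters
    ----------
    spec : BinSpec, optional
        Bin centers; defaults to the standard constants.
    apply_sqrt : bool, default True
        Square-root transform each entry (variance stabilisation against
        long-tailed pixel counts).
    mode : {"triangular", "nearest"}, default "triangular"
        Mass assignment between bin centers.
    """

    def __init__(
        self,
        spec: BinSpec | None = None,
        apply_sqrt: bool = True,
        mode: BinningMode = "triangular",
    ) -> None:
        self.spec = spec
        self.apply_sqrt = apply_sqrt
        self.mode = mode

    def fit(self, X: Sequence[LineDrawing], y=None) -> "ContourFeatureExtractor":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Sequence[LineDrawing]) -> np.ndarray:
        spec = self.spec or BinSpec()
        return np.array(
            [feature_vector(d, spec, self.apply_sqrt, self.mode).values for d in X]
        )

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(FEATURE_NAMES, dtype=object)


def feature_table(
    drawings: Sequence[LineDrawing],
    image_ids: Sequence[str],
    spec: BinSpec | None = None,
    apply_sqrt: bool = True,
    mode: BinningMode = "triangular",
) -> pd.DataFrame:
    """Feature matrix as a DataFrame: one row per drawing, image_id first."""
    if len(drawings) != len(image_ids):
        raise ValueError("drawings and image_ids must have equal length")
    X = ContourFeatureExtractor(spec, apply_sqrt, mode).fit(drawings).transform(drawings)
    df = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    df.insert(0, "image_id", list(image_ids))
    df.attrs["sqrt_applied"] = apply_sqrt
    return df
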