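"""Construction of abstract scene stimuli from binned contour pools.

Contours harvested from full-size (800x600) line drawings are classified
into a 2 x 3 x 4 factorial of feature bins — Length (short, long) x
Angularity (low, medium, high) x Orientation (horizontal, vertical, both,
diagonal) — and assembled into small 200x150 abstract images: contours are
sampled from one bin, scaled down by 4, shifted (and if necessary
shortened) to fit the canvas, and appended until the image's total contour
length exceeds a fixed pixel budget.  The default set is 20 images per bin,
480 images in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    Contour,
    LineDrawing,
    contour_length,
    fold_orientation,
    folded_mean_orientation,
    segment_lengths,
    segment_orientations,
    vertex_angularities,
)

__all__ = [
    "BinLabel",
    "BinThresholds",
    "StimulusImage",
    "EmptyBinError",
    "ALL_BINS",
    "LENGTH_CLASSES",
    "ANGULARITY_CLASSES",
    "ORIENTATION_CLASSES",
    "classify_contour",
    "build_contour_pool",
    "place_contour",
    "generate_images_for_bin",
    "generate_stimulus_set",
    "stimulus_manifest",
]

LENGTH_CLASSES = ("short", "long")
ANGULARITY_CLASSES = ("low", "medium", "high")
ORIENTATION_CLASSES = ("horizontal", "vertical", "both", "diagonal")


@dataclass(frozen=True, order=True)
class BinLabel:
    """One cell of the length x angularity x orientation factorial."""

    length_class: str
    angularity_class: str
    orientation_class: str

    def __post_init__(self) -> None:
        if self.length_class not in LENGTH_CLASSES:
            raise ValueError(f"unknown length class {self.length_class!r}")
        if self.angularity_class not in ANGULARITY_CLASSES:
            raise ValueError(f"unknown angularity class {self.angularity_class!r}")
        if self.orientation_class not in ORIENTATION_CLASSES:
            raise ValueError(f"unknown orientation class {self.orientation_class!r}")

    def __str__(self) -> str:
        return f"{self.length_class}-{self.angularity_class}-{self.orientation_class}"


#: All 24 bin labels in deterministic (sorted) order.
ALL_BINS: tuple[BinLabel, ...] = tuple(
    sorted(
        BinLabel(l, a, o)
        for l, a, o in itertools.product(
            LENGTH_CLASSES, ANGULARITY_CLASSES, ORIENTATION_CLASSES
        )
    )
)


@dataclass(frozen=True)
class BinThresholds:
    """Cut values mapping continuous contour features onto the 24 bins.

    Defaults reuse the histogram bin geometry: the length split and the two
    angularity splits sit on log-spaced histogram centers, and the
    orientation band is the histogram bin half-spacing.

    * ``length_split`` — contours at or above it are "long" (pixels);
    * ``angularity_splits`` — mean vertex angularity below the first is
      "low", above the second "high" (degrees/pixel);
    * ``orientation_band`` — folded mean orientation within the band of 0
      is "horizontal", within the band of 90 "vertical" (degrees);
    * ``extreme_fraction`` — among the remaining contours, those whose
      pixel-weighted fraction of near-horizontal or near-vertical segments
      exceeds it are "both", the rest "diagonal".
    """

    length_split: float = 87.10
    angularity_splits: tuple[float, float] = (5.13, 35.48)
    orientation_band: float = 22.5
    extreme_fraction: float = 0.5

    def __post_init__(self) -> None:
        a1, a2 = self.angularity_splits
        if not a1 < a2:
            raise ValueError("angularity_splits must be strictly increasing")
        if not 0 < self.orientation_band < 45:
            raise ValueError("orientation_band must lie in (0, 45)")
        if not 0 <= self.extreme_fraction <= 1:
            raise ValueError("extreme_fraction must lie in [0, 1]")
        if self.length_split <= 0:
            raise ValueError("length_split must be positive")


@dataclass(frozen=True)
class StimulusImage:
    """One generated abstract scene with its bin label and provenance."""

    image_id: str
    bin: BinLabel
    drawing: LineDrawing
    total_length: float
    provenance: tuple[tuple[str, str], ...]  # (source contour id, adjustment)


class EmptyBinError(ValueError):
    """Raised when stimulus generation is asked to draw from an empty bin."""


def classify_contour(contour: Contour, thresholds: BinThresholds | None = None) -> BinLabel:
    """Assign a contour to its (length, angularity, orientation) bin."""
    t = thresholds or BinThresholds()
    length = contour_length(contour)
    length_class = "long" if length >= t.length_split else "short"

    ang = vertex_angularities(contour)
    mean_ang = float(ang.mean()) if len(ang) else 0.0
    a1, a2 = t.angularity_splits
    if mean_ang < a1:
        angularity_class = "low"
    elif mean_ang < a2:
        angularity_class = "medium"
    else:
        angularity_class = "high"

    folded_mean = folded_mean_orientation(contour)
    if folded_mean < t.orientation_band:
        orientation_class = "horizontal"
    elif folded_mean > 90.0 - t.orientation_band:
        orientation_class = "vertical"
    else:
        folded = np.asarray(fold_orientation(segment_orientations(contour)))
        w = segment_lengths(contour)
        extreme = (folded <= t.orientation_band) | (folded >= 90.0 - t.orientation_band)
        frac = float(w[extreme].sum() / w.sum())
        orientation_class = "both" if frac > t.extreme_fraction else "diagonal"
    return BinLabel(length_class, angularity_class, orientation_class)


def build_contour_pool(
    drawings: Sequence[LineDrawing],
    thresholds: BinThresholds | None = None,
) -> dict[BinLabel, list[Contour]]:
    """Partition every contour of the drawings into its feature bin.

    Every bin label appears as a key (possibly with an empty list), so the
    caller can see which bins are unpopulated.
    """
    if not drawings:
        raise ValueError("cannot build a contour pool from an empty drawing list")
    pool: dict[BinLabel, list[Contour]] = {b: [] for b in ALL_BINS}
    for d in drawings:
        for c in d.contours:
            pool[classify_contour(c, thresholds)].append(c)
    return pool


Adjustment = Literal["as-is", "shifted", "shortened"]


def place_contour(
    contour: Contour,
    canvas_width: float = 200.0,
    canvas_height: float = 150.0,
    scale: float = 4.0,
) -> tuple[Contour, Adjustment] | None:
    """Scale a contour down and fit it onto the stimulus canvas.

    Coordinates are divided by ``scale``.  If the scaled contour pokes out
    of the canvas it is shifted by the minimal offset that brings its
    bounding box inside; if the bounding box is larger than the canvas in
    either dimension, points are truncated from the tail end until it fits,
    then shifted.  Returns ``None`` (a skip signal) if truncation leaves
    fewer than 2 points.
    """
    pts = contour.points / scale
    n = len(pts)
    adjustment: Adjustment = "as-is"
    # truncate from the tail until the bbox can fit at all
    while n >= 2:
        span = pts[:n].max(axis=0) - pts[:n].min(axis=0)
        if span[0] <= canvas_width and span[1] <= canvas_height:
            break
        n -= 1
        adjustment = "shortened"
    if n < 2:
        return None
    pts = pts[:n]
    lo = pts.min(axis=0)
    hi = pts.max(axis=0)
    shift = np.zeros(2)
    shift[0] = -lo[0] if lo[0] < 0 else min(0.0, canvas_width - hi[0])
    shift[1] = -lo[1] if lo[1] < 0 else min(0.0, canvas_height - hi[1])
    if adjustment == "as-is" and np.any(shift != 0.0):
        adjustment = "shifted"
    return Contour(pts + shift, id=contour.id), adjustment


def generate_images_for_bin(
    pool: Mapping[BinLabel, Sequence[Contour]],
    bin: BinLabel,
    n_images: int = 20,
    length_budget: float = 1000.0,
    canvas_width: float = 200.0,
    canvas_height: float = 150.0,
    scale: float = 4.0,
    rng: np.random.Generator | int | None = None,
) -> list[StimulusImage]:
    """Assemble ``n_images`` stimuli from one bin's contour pool.

    Contours are sampled uniformly without replacement within an image
    (with replacement across images); each is scaled, shifted/shortened
    onto the canvas and appended until the summed placed contour length
    exceeds ``length_budget``.
    """
    rng = np.random.default_rng(rng)
    contours = list(pool.get(bin, ()))
    if not contours:
        raise EmptyBinError(f"bin {bin} has no contours to sample from")
    images: list[StimulusImage] = []
    for i in range(n_images):
        order = rng.permutation(len(contours))
        placed: list[Contour] = []
        provenance: list[tuple[str, str]] = []
        total = 0.0
        idx = 0
        while total <= length_budget:
            if idx >= len(order):
                raise EmptyBinError(
                    f"bin {bin}: pool exhausted at {total:.0f} px, cannot exceed "
                    f"the {length_budget:.0f} px budget"
                )
            src = contours[order[idx]]
            idx += 1
            result = place_contour(src, canvas_width, canvas_height, scale)
            if result is None:
                continue
            c, adj = result
            placed.append(Contour(c.points, id=f"c{len(placed)}"))
            provenance.append((src.id, adj))
            total += contour_length(c)
        images.append(
            StimulusImage(
                image_id=f"{bin}_{i + 1:02d}",
                bin=bin,
                drawing=LineDrawing(tuple(placed), canvas_width, canvas_height),
                total_length=total,
                provenance=tuple(provenance),
            )
        )
    return images


def generate_stimulus_set(
    pool: Mapping[BinLabel, Sequence[Contour]],
    n_per_bin: int = 20,
    length_budget: float = 1000.0,
    canvas_width: float = 200.0,
    canvas_height: float = 150.0,
    scale: float = 4.0,
    seed: int | None = None,
) -> list[StimulusImage]:
    """Generate the full factorial stimulus set (24 bins x ``n_per_bin``)."""
    missing = [str(b) for b in ALL_BINS if not pool.get(b)]
    if missing:
        raise EmptyBinError(f"pool has empty bins: {missing}")
    rng = np.random.default_rng(seed)
    images: list[StimulusImage] = []
    for b in ALL_BINS:  # sorted order makes the set seed-deterministic
        images.extend(
            generate_images_for_bin(
                pool, b, n_per_bin, length_budget,
                canvas_width, canvas_height, scale, rng,
            )
        )
    return images


def stimulus_manifest(images: Sequence[StimulusImage], seed: int | None = None) -> pd.DataFrame:
    """Manifest table: one row per stimulus image."""
    rows = [
        {
            "image_id": img.image_id,
            "length_class": img.bin.length_class,
            "angularity_class": img.bin.angularity_class,
            "orientation_class": img.bin.orientation_class,
            "n_contours": img.drawing.n_contours,
            "total_length": round(img.total_length, 6),
            "seed": seed if seed is not None else "",
        }
        for img in images
    ]
    return pd.DataFrame(rows)
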