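"""Synthetic inputs for the whole pipeline.

Three generators, all seed-deterministic:

* controlled contours and drawings — zig-zag random walks whose heading,
  turn amplitude and segment scale are chosen so the realized contour falls
  in a requested (length x angularity x orientation) feature bin;
* valence datasets — drawings plus mean ratings produced by a known linear
  model over the square-root feature matrix with Gaussian noise, clipped to
  the 1-9 Likert range;
* forced-choice sessions — simulated observers with additive cell
  utilities, a Gaussian participant intercept, and either a Gumbel-noise
  argmax/argmin rule over each 4-image trial (realistic 4AFC behaviour) or
  a "bernoulli-direct" mode that draws each binary outcome straight from
  the random-intercept logistic model (for exact recovery tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .geometry import Contour, LineDrawing
from .histograms import FEATURE_NAMES, ContourFeatureExtractor
from .stimuli import ALL_BINS, BinLabel, BinThresholds
from .glmm import FACTOR_COLUMNS, design_matrix

__all__ = [
    "ContourRecipe",
    "ObserverSpec",
    "default_recipe",
    "synth_contour",
    "synth_pool",
    "synth_valence_dataset",
    "synth_choice_session",
    "DEFAULT_BETA_TRUE",
]

# turn half-amplitude a (degrees) and segment scale s (pixels) per
# angularity class; vertices turn by ~2a, so mean angularity ~ 2a / s.
_ZIGZAG_PARAMS: dict[str, tuple[float, float]] = {
    "low": (6.0, 10.0),
    "medium": (15.0, 2.0),
    "high": (15.0, 0.6),
}
# the "both" orientation class alternates 0/90-degree segments, so every
# turn is ~90 degrees and only the segment scale controls angularity.
_BOTH_SEGMENT_SCALE: dict[str, float] = {"low": 30.0, "medium": 9.0, "high": 1.6}

_BASE_HEADING: dict[str, float] = {"horizontal": 0.0, "vertical": 90.0, "diagonal": 45.0}

_SHORT_LENGTH_RANGE = (45.0, 70.0)
_LONG_LENGTH_RANGE = (150.0, 300.0)


@dataclass(frozen=True)
class ContourRecipe:
    """Parameters of one synthetic zig-zag contour."""

    bin: BinLabel
    target_length: float
    turn_scale: float  # full turn per vertex, degrees
    segment_scale: float  # nominal segment length, pixels
    heading: float  # base heading, degrees in [0, 180)

    def __post_init__(self) -> None:
        if self.target_length <= 0 or self.segment_scale <= 0:
            raise ValueError("target_length and segment_scale must be positive")
        if not 0 <= self.heading < 180:
            raise ValueError("heading must lie in [0, 180)")


def default_recipe(bin: BinLabel, rng: np.random.Generator) -> ContourRecipe:
    """Draw a recipe whose realized contour lands in ``bin``."""
    lo, hi = (
        _SHORT_LENGTH_RANGE if bin.length_class == "short" else _LONG_LENGTH_RANGE
    )
    target = float(rng.uniform(lo, hi))
    if bin.orientation_class == "both":
        s = _BOTH_SEGMENT_SCALE[bin.angularity_class]
        turn, heading = 90.0, 0.0
    else:
        a, s = _ZIGZAG_PARAMS[bin.angularity_class]
        turn = 2.0 * a
        heading = _BASE_HEADING[bin.orientation_class]
        if bin.orientation_class == "diagonal" and rng.random() < 0.5:
            heading = 135.0
    return ContourRecipe(bin, target, turn, s, heading)


def _recipe_headings(recipe: ContourRecipe, n_seg: int, rng: np.random.Generator) -> np.ndarray:
    k = np.arange(n_seg)
    if recipe.bin.orientation_class == "both":
        base = np.where(k % 2 == 0, 0.0, 90.0)
        return base + rng.uniform(-2.0, 2.0, n_seg)
    amp = recipe.turn_scale / 2.0
    return recipe.heading + amp * (-1.0) ** k + rng.uniform(-3.0, 3.0, n_seg)


def synth_contour(
    recipe: ContourRecipe,
    rng: np.random.Generator | int | None = None,
    canvas_width: float = 800.0,
    canvas_height: float = 600.0,
    id: str = "",
) -> Contour:
    """A zig-zag polyline realizing the recipe, placed on the canvas.

    Segment lengths are jittered and then rescaled so the total contour
    length equals ``target_length`` exactly; the contour's bounding box is
    translated to a uniform random position inside the canvas.
    """
    rng = np.random.default_rng(rng)
    n_seg = max(2, int(round(recipe.target_length / recipe.segment_scale)))
    lengths = rng.uniform(0.85, 1.15, n_seg)
    lengths *= recipe.target_length / lengths.sum()
    headings = np.radians(_recipe_headings(recipe, n_seg, rng))
    steps = np.column_stack(
        [lengths * np.cos(headings), -lengths * np.sin(headings)]  # y-down canvas
    )
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    if span[0] > canvas_width or span[1] > canvas_height:
        raise ValueError(
            f"recipe produces a {span[0]:.0f}x{span[1]:.0f} px contour that "
            f"cannot fit the {canvas_width}x{canvas_height} canvas"
        )
    origin = np.array(
        [
            rng.uniform(0.0, canvas_width - span[0]),
            rng.uniform(0.0, canvas_height - span[1]),
        ]
    )
    return Contour(pts - lo + origin, id=id)


def synth_pool(
    n_per_bin: int = 150,
    seed: int | np.random.Generator | None = None,
    canvas_width: float = 800.0,
    canvas_height: float = 600.0,
    contours_per_drawing: int = 8,
    thresholds: BinThresholds | None = None,
) -> list[LineDrawing]:
    """Drawings jointly containing >= ``n_per_bin`` contours of every bin.

    Contours are generated bin by bin, shuffled, and packed into drawings of
    ``contours_per_drawing`` contours each on a full-size canvas, emulating
    the traced scene drawings the stimulus pipeline starts from.
    """
    if n_per_bin < 1:
        raise ValueError("n_per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    contours: list[Contour] = []
    for b in ALL_BINS:
        for i in range(n_per_bin):
            recipe = default_recipe(b, rng)
            contours.append(
                synth_contour(recipe, rng, canvas_width, canvas_height, id=f"{b}_{i}")
            )
    order = rng.permutation(len(contours))
    drawings = []
    for start in range(0, len(contours), contours_per_drawing):
        chunk = [contours[j] for j in order[start : start + contours_per_drawing]]
        if chunk:
            drawings.append(LineDrawing(tuple(chunk), canvas_width, canvas_height))
    return drawings


def _speck_contour(
    rng: np.random.Generator,
    canvas_width: float,
    canvas_height: float,
    id: str = "",
) -> Contour:
    """A small free-form contour with random headings and turn angles.

    The bin recipes produce stereotyped contours whose lengths and turn
    rates cluster inside their class ranges; rating datasets additionally
    need mass in the extreme histogram bins (very short contours, very
    sharp turns), which these specks provide.
    """
    n_seg = int(rng.integers(1, 5))
    lengths = rng.uniform(0.6, 1.0, n_seg) * float(np.exp(rng.uniform(0.0, 2.8)))
    headings = np.radians(rng.uniform(0.0, 180.0, n_seg))
    steps = np.column_stack([lengths * np.cos(headings), -lengths * np.sin(headings)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo
    origin = np.array(
        [
            rng.uniform(0.0, canvas_width - span[0]),
            rng.uniform(0.0, canvas_height - span[1]),
        ]
    )
    return Contour(pts - lo + origin, id=id)


#: Default true coefficients of the rating model: only the long-contour,
#: high-angularity and vertical-orientation features carry (small) signal.
DEFAULT_BETA_TRUE: np.ndarray = np.zeros(23)
DEFAULT_BETA_TRUE[FEATURE_NAMES.index("O5")] = -0.03
DEFAULT_BETA_TRUE[FEATURE_NAMES.index("L7")] = 0.01
DEFAULT_BETA_TRUE[FEATURE_NAMES.index("A8")] = -0.08
DEFAULT_BETA_TRUE.setflags(write=False)


def synth_valence_dataset(
    n_images: int = 1182,
    beta_true: np.ndarray | None = None,
    noise_sd: float = 1.0,
    seed: int | np.random.Generator | None = None,
    canvas_width: float = 800.0,
    canvas_height: float = 600.0,
) -> tuple[list[LineDrawing], pd.DataFrame]:
    """Drawings plus ratings generated from a known linear feature model.

    Each drawing holds 6-14 contours of random feature bins.  Ratings are
    ``clip(5 + (X - mean(X)) beta_true + N(0, noise_sd), 1, 9)`` with X the
    square-root feature matrix; centering keeps the mean rating at
    mid-scale so that clipping (reported in ``ratings.attrs``) stays rare
    and the slopes recoverable.  The first half of the images is labelled
    "close", the second half "far".
    """
    if n_images <= 25:
        raise ValueError("need more than 25 images to fit 23 predictors")
    beta = DEFAULT_BETA_TRUE if beta_true is None else np.asarray(beta_true, float)
    if beta.shape != (23,):
        raise ValueError("beta_true must have 23 entries")
    rng = np.random.default_rng(seed)
    drawings: list[LineDrawing] = []
    for i in range(n_images):
        n_contours = int(rng.integers(6, 15))
        bins = rng.integers(0, len(ALL_BINS), n_contours)
        cs = [
            synth_contour(
                default_recipe(ALL_BINS[b], rng), rng,
                canvas_width, canvas_height, id=f"img{i}_c{j}",
            )
            for j, b in enumerate(bins)
        ]
        cs += [
            _speck_contour(rng, canvas_width, canvas_height, id=f"img{i}_s{j}")
            for j in range(int(rng.integers(3, 9)))
        ]
        drawings.append(LineDrawing(tuple(cs), canvas_width, canvas_height))
    X = ContourFeatureExtractor(apply_sqrt=True).fit(drawings).transform(drawings)
    ratings = ratings_from_features(
        X, beta, noise_sd, rng, image_ids=[f"img{i}" for i in range(n_images)]
    )
    return drawings, ratings


def ratings_from_features(
    X: np.ndarray,
    beta_true: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator | int | None = None,
    image_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Ratings from the linear model over a pre-computed feature matrix.

    Useful for replicate simulations that hold the drawings (and hence X)
    fixed while redrawing the rating noise.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, float)
    n = len(X)
    signal = (X - X.mean(axis=0)) @ np.asarray(beta_true, float)
    raw = 5.0 + signal + rng.normal(0.0, noise_sd, n)
    valence = np.clip(raw, 1.0, 9.0)
    ratings = pd.DataFrame(
        {
            "image_id": list(image_ids) if image_ids is not None
            else [f"img{i}" for i in range(n)],
            "valence": valence,
            "distance_class": ["close"] * (n // 2) + ["far"] * (n - n // 2),
        }
    )
    ratings.attrs["clip_fraction"] = float(np.mean(raw != valence))
    ratings.attrs["beta_true"] = np.asarray(beta_true, float)
    return ratings


@dataclass(frozen=True)
class ObserverSpec:
    """Additive cell utilities and noise structure of a simulated observer.

    Utilities are on the logit scale; per-level dictionaries are summed
    into a utility for each of the 24 cells, plus optional interaction
    offsets keyed by (length, angularity, orientation).  ``intercept_sd``
    is the participant random-intercept standard deviation.
    """

    length_utils: Mapping[str, float] = field(
        default_factory=lambda: {"short": -0.4, "long": 0.4}
    )
    angularity_utils: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.5, "medium": 0.0, "high": -0.5}
    )
    orientation_utils: Mapping[str, float] = field(
        default_factory=lambda: {
            "horizontal": 0.6, "vertical": -0.2, "both": -0.2, "diagonal": -0.2,
        }
    )
    interaction_utils: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    intercept_sd: float = 0.5
    decision_rule: Literal["gumbel", "bernoulli"] = "gumbel"

    def __post_init__(self) -> None:
        if self.intercept_sd < 0:
            raise ValueError("intercept_sd must be >= 0")

    @classmethod
    def threat_default(cls) -> "ObserverSpec":
        """Observer whose strongest cue is contour length (threat task)."""
        return cls(
            length_utils={"short": -0.8, "long": 0.8},
            angularity_utils={"low": 0.4, "medium": 0.0, "high": -0.4},
            orientation_utils={
                "horizontal": 0.45, "vertical": -0.15, "both": -0.15, "diagonal": -0.15,
            },
        )

    def cell_utility(self, length: str, angularity: str, orientation: str) -> float:
        return (
            self.length_utils[length]
            + self.angularity_utils[angularity]
            + self.orientation_utils[orientation]
            + self.interaction_utils.get((length, angularity, orientation), 0.0)
        )

    def cell_table(self) -> pd.DataFrame:
        rows = [
            {
                "length_class": b.length_class,
                "angularity_class": b.angularity_class,
                "orientation_class": b.orientation_class,
                "utility": self.cell_utility(
                    b.length_class, b.angularity_class, b.orientation_class
                ),
            }
            for b in ALL_BINS
        ]
        return pd.DataFrame(rows)

    def true_fixed_effects(self) -> tuple[list[str], np.ndarray]:
        """The sum-coded fixed-effect vector implied by the cell utilities."""
        cells = self.cell_table()
        X, names, _ = design_matrix(cells)
        beta, *_ = np.linalg.lstsq(X, cells["utility"].to_numpy(), rcond=None)
        return names, beta


def _manifest_utilities(manifest: pd.DataFrame, observer: ObserverSpec) -> np.ndarray:
    return np.array(
        [
            observer.cell_utility(l, a, o)
            for l, a, o in manifest[list(FACTOR_COLUMNS)].itertuples(index=False)
        ]
    )


def synth_choice_session(
    manifest: pd.DataFrame,
    observer: ObserverSpec | None = None,
    n_participants: int = 157,
    seed: int | np.random.Generator | None = None,
    task: Literal["valence", "threat"] = "valence",
    n_trials: int | None = None,
) -> pd.DataFrame:
    """Simulate forced-choice sessions over a stimulus manifest.

    With the default Gumbel rule, each participant sees every image exactly
    once, in a random partition of the set into 4-image trials; the images
    with the highest and lowest utility-plus-Gumbel-noise are selected as
    most positive/safe and most negative/threatening.  Returns a trial
    table (participant_id, task, trial_index, img1..img4, choice_high,
    choice_low).

    With ``observer.decision_rule == "bernoulli"`` the function instead
    returns long-format choice observations whose outcomes are drawn
    directly from the random-intercept logistic model (two observations per
    nominal trial position), for exact parameter-recovery tests.
    """
    observer = observer or ObserverSpec()
    rng = np.random.default_rng(seed)
    ids = manifest["image_id"].to_numpy()
    if len(ids) % 4 != 0:
        raise ValueError(f"manifest size {len(ids)} is not divisible by 4")
    util = _manifest_utilities(manifest, observer)
    total_trials = len(ids) // 4 if n_trials is None else n_trials

    if observer.decision_rule == "bernoulli":
        rows = []
        for p in range(n_participants):
            b = rng.normal(0.0, observer.intercept_sd)
            order = rng.permutation(len(ids))[: 4 * total_trials]
            eta = util[order] + b
            outcome = rng.random(len(order)) < special.expit(eta)
            rows.append(
                pd.DataFrame(
                    {
                        "participant_id": f"p{p + 1:03d}",
                        "trial_index": np.repeat(
                            np.arange(1, total_trials + 1), 4
                        ),
                        "image_id": ids[order],
                        "outcome": outcome.astype(int),
                    }
                )
            )
        obs = pd.concat(rows, ignore_index=True)
        return obs.merge(
            manifest[["image_id", *FACTOR_COLUMNS]], on="image_id", validate="m:1"
        )

    records = []
    for p in range(n_participants):
        order = rng.permutation(len(ids)).reshape(-1, 4)[:total_trials]
        noise = rng.gumbel(0.0, 1.0, order.shape)
        u = util[order] + noise
        hi = ids[np.take_along_axis(order, u.argmax(1, keepdims=True), 1)[:, 0]]
        lo = ids[np.take_along_axis(order, u.argmin(1, keepdims=True), 1)[:, 0]]
        shown = ids[order]
        records.append(
            pd.DataFrame(
                {
                    "participant_id": f"p{p + 1:03d}",
                    "task": task,
                    "trial_index": np.arange(1, len(order) + 1),
                    "img1": shown[:, 0],
                    "img2": shown[:, 1],
                    "img3": shown[:, 2],
                    "img4": shown[:, 3],
                    "choice_high": hi,
                    "choice_low": lo,
                }
            )
        )
    return pd.concat(records, ignore_index=True)
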