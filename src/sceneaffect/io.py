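"""File formats: the drawing JSON dialect, SVG polylines, CSV tables,
run configuration and run records.

The drawing document is a small JSON dialect::

    {"schema_version": 1,
     "canvas": {"width": 800, "height": 600},
     "contours": [{"id": "c0", "points": [[x, y], ...]}, ...]}

Coordinates are serialized with 6 decimal digits; read(write(d)) reproduces
them exactly at that precision.  Schema violations are reported with a
JSON-path-style locator (e.g. ``contours[3].points[0]``).

SVG support covers exactly what the stimuli need: ``<polyline>`` elements
and ``<path>`` data restricted to move/line commands; curved commands are
rejected, not approximated.
"""

from __future__ import annotations

import hashlib
import json
import re
import sys
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import Contour, InvalidContourError, LineDrawing
from .stimuli import BinThresholds, StimulusImage

__all__ = [
    "DrawingFormatError",
    "UnsupportedGeometryError",
    "RunConfig",
    "read_drawing",
    "write_drawing",
    "drawing_to_document",
    "document_to_drawing",
    "import_svg",
    "write_stimulus_svg",
    "write_run_record",
    "read_trials_csv",
    "read_ratings_csv",
]

SCHEMA_VERSION = 1
_PRECISION = 6


class DrawingFormatError(ValueError):
    """Malformed or schema-violating drawing document."""


class UnsupportedGeometryError(ValueError):
    """SVG input contains geometry other than straight polylines."""


# ---------------------------------------------------------------------------
# drawing JSON dialect


def drawing_to_document(drawing: LineDrawing) -> dict[str, Any]:
    return {
        "schema_version": SCHEMA_VERSION,
        "canvas": {"width": drawing.canvas_width, "height": drawing.canvas_height},
        "contours": [
            {
                "id": c.id,
                "points": [
                    [round(float(x), _PRECISION), round(float(y), _PRECISION)]
                    for x, y in c.points
                ],
            }
            for c in drawing.contours
        ],
    }


def document_to_drawing(doc: dict[str, Any]) -> LineDrawing:
    def fail(path: str, msg: str) -> None:
        raise DrawingFormatError(f"{path}: {msg}")

    if not isinstance(doc, dict):
        fail("$", "document must be a JSON object")
    canvas = doc.get("canvas")
    if not isinstance(canvas, dict) or "width" not in canvas or "height" not in canvas:
        fail("canvas", "must be an object with 'width' and 'height'")
    width, height = canvas["width"], canvas["height"]
    contours_doc = doc.get("contours")
    if not isinstance(contours_doc, list) or not contours_doc:
        fail("contours", "must be a non-empty list")
    contours = []
    for i, c in enumerate(contours_doc):
        loc = f"contours[{i}]"
        if not isinstance(c, dict) or "points" not in c:
            fail(loc, "must be an object with a 'points' list")
        pts = c["points"]
        if not isinstance(pts, list) or len(pts) < 2:
            fail(f"{loc}.points", "needs at least 2 [x, y] pairs")
        for j, p in enumerate(pts):
            if (
                not isinstance(p, (list, tuple))
                or len(p) != 2
                or not all(isinstance(v, (int, float)) for v in p)
            ):
                fail(f"{loc}.points[{j}]", "must be a numeric [x, y] pair")
            if p[0] < 0 or p[1] < 0 or p[0] > width or p[1] > height:
                fail(
                    f"{loc}.points[{j}]",
                    f"point ({p[0]}, {p[1]}) lies outside the "
                    f"{width}x{height} canvas",
                )
        try:
            contours.append(Contour(np.asarray(pts, float), id=str(c.get("id", f"c{i}"))))
        except InvalidContourError as err:
            fail(loc, str(err))
    try:
        return LineDrawing(tuple(contours), float(width), float(height))
    except InvalidContourError as err:
        raise DrawingFormatError(f"$: {err}") from err


def write_drawing(drawing: LineDrawing, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(drawing_to_document(drawing), indent=1), encoding="utf-8"
    )


def read_drawing(path: str | Path) -> LineDrawing:
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as err:
        raise DrawingFormatError(f"{path}: not valid JSON ({err})") from err
    return document_to_drawing(doc)


# ---------------------------------------------------------------------------
# SVG

_SVG_NS = "http://www.w3.org/2000/svg"
_PATH_TOKEN = re.compile(r"([MmLlHhVvZzCcSsQqTtAa])|(-?\d*\.?\d+(?:[eE][-+]?\d+)?)")


def write_stimulus_svg(image: StimulusImage, path: str | Path) -> None:
    """One black 1-px polyline per contour, viewBox matching the canvas."""
    d = image.drawing
    svg = ET.Element(
        "svg",
        xmlns=_SVG_NS,
        viewBox=f"0 0 {d.canvas_width:g} {d.canvas_height:g}",
        width=f"{d.canvas_width:g}",
        height=f"{d.canvas_height:g}",
    )
    for c in d.contours:
        ET.SubElement(
            svg,
            "polyline",
            points=" ".join(
                f"{float(x):.{_PRECISION}f},{float(y):.{_PRECISION}f}"
                for x, y in c.points
            ),
            fill="none",
            stroke="black",
            attrib={"stroke-width": "1", "data-id": c.id},
        )
    ET.ElementTree(svg).write(path, encoding="unicode", xml_declaration=True)


def _parse_points_attr(text: str) -> np.ndarray:
    nums = [float(v) for v in re.split(r"[\s,]+", text.strip()) if v]
    if len(nums) < 4 or len(nums) % 2:
        raise UnsupportedGeometryError(f"malformed polyline points: {text!r}")
    return np.asarray(nums, float).reshape(-1, 2)


def _parse_path_data(d: str) -> list[np.ndarray]:
    """Absolute/relative move-line-close path data -> list of point arrays."""
    tokens = _PATH_TOKEN.findall(d)
    polylines: list[list[list[float]]] = []
    current: list[list[float]] = []
    pos = [0.0, 0.0]
    cmd = None
    nums: list[float] = []

    def flush() -> None:
        nonlocal current
        if len(current) >= 2:
            polylines.append(current)
        current = []

    i = 0
    flat: list[tuple[str | None, float | None]] = [
        (c if c else None, float(n) if n else None) for c, n in tokens
    ]
    while i < len(flat):
        c, n = flat[i]
        if c is not None:
            if c in "CcSsQqTtAa":
                raise UnsupportedGeometryError(
                    f"path command {c!r} (curve/arc) is not supported; only "
                    "straight move/line segments can be imported"
                )
            cmd = c
            i += 1
            if cmd in "Zz":
                if current:
                    current.append(list(current[0]))
                flush()
            continue
        if cmd is None:
            raise UnsupportedGeometryError("path data does not start with a command")
        if cmd in "HhVv":
            v = n
            i += 1
            x, y = pos
            if cmd == "H":
                x = v
            elif cmd == "h":
                x += v
            elif cmd == "V":
                y = v
            else:
                y += v
            pos = [x, y]
            current.append(list(pos))
            continue
        x, y = n, flat[i + 1][1]
        i += 2
        if cmd in "ml":
            x, y = pos[0] + x, pos[1] + y
        if cmd in "Mm":
            flush()
            pos = [x, y]
            current = [list(pos)]
            cmd = "L" if cmd == "M" else "l"
        else:
            pos = [x, y]
            current.append(list(pos))
    flush()
    return [np.asarray(p) for p in polylines]


def import_svg(path: str | Path) -> LineDrawing:
    """Read polyline/line-only-path SVG into a LineDrawing.

    The canvas is taken from the viewBox (falling back to width/height);
    curved path commands raise :class:`UnsupportedGeometryError`.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    viewbox = root.get("viewBox")
    if viewbox:
        _, _, w, h = (float(v) for v in viewbox.replace(",", " ").split())
    else:
        w = float(re.sub(r"[a-z%]+$", "", root.get("width", "0")))
        h = float(re.sub(r"[a-z%]+$", "", root.get("height", "0")))
    if w <= 0 or h <= 0:
        raise DrawingFormatError(f"{path}: SVG has no usable viewBox or width/height")
    contours: list[Contour] = []
    k = 0
    for el in root.iter():
        tag = el.tag.split("}")[-1]
        if tag == "polyline":
            pts = _parse_points_attr(el.get("points", ""))
            contours.append(Contour(pts, id=el.get("data-id", f"c{k}")))
            k += 1
        elif tag == "path":
            for pts in _parse_path_data(el.get("d", "")):
                contours.append(Contour(pts, id=el.get("data-id", f"c{k}")))
                k += 1
        elif tag in ("circle", "ellipse", "rect"):
            raise UnsupportedGeometryError(
                f"SVG element <{tag}> is not supported; only polylines and "
                "straight-line paths can be imported"
            )
    if not contours:
        raise DrawingFormatError(f"{path}: SVG contains no polyline geometry")
    return LineDrawing(tuple(contours), w, h)


# ---------------------------------------------------------------------------
# configuration and run records


@dataclass(frozen=True)
class RunConfig:
    """Validated pipeline settings (defaults are the method's constants)."""

    n_per_bin: int = 20
    length_budget: float = 1000.0
    canvas_width: float = 200.0
    canvas_height: float = 150.0
    scale: float = 4.0
    pool_n_per_bin: int = 150
    length_split: float = 87.10
    angularity_splits: tuple[float, float] = (5.13, 35.48)
    orientation_band: float = 22.5
    extreme_fraction: float = 0.5
    random_structure: str = "participant"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_bin < 1:
            raise ValueError("n_per_bin must be a positive count")
        if self.length_budget < 0:
            raise ValueError("length_budget must be >= 0 pixels")
        if self.canvas_width <= 0 or self.canvas_height <= 0:
            raise ValueError("canvas dimensions must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.random_structure not in ("participant", "participant+trial"):
            raise ValueError(
                f"random_structure must be 'participant' or 'participant+trial', "
                f"got {self.random_structure!r}"
            )
        BinThresholds(  # reuses its validation
            self.length_split,
            tuple(self.angularity_splits),
            self.orientation_band,
            self.extreme_fraction,
        )

    def thresholds(self) -> BinThresholds:
        return BinThresholds(
            self.length_split,
            tuple(self.angularity_splits),
            self.orientation_band,
            self.extreme_fraction,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "angularity_splits" in data:
            data["angularity_splits"] = tuple(data["angularity_splits"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["angularity_splits"] = list(data["angularity_splits"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    def config_hash(self) -> str:
        data = asdict(self)
        data["angularity_splits"] = list(data["angularity_splits"])
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


def write_run_record(out_dir: str | Path, config: RunConfig, extra: dict | None = None) -> Path:
    """Machine-readable record of a run next to its outputs."""
    record = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        **(extra or {}),
    }
    path = Path(out_dir) / "run_record.json"
    path.write_text(json.dumps(record, indent=1), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# CSV readers (writers are plain DataFrame.to_csv at the call sites)


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    import warnings

    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{what} has unknown columns (ignored): {extra}", stacklevel=2)


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, ["image_id", "valence", "distance_class"], "ratings CSV")
    return df


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Trial records; rows with a missing choice are dropped and counted."""
    df = pd.read_csv(path)
    _check_columns(
        df,
        [
            "participant_id", "task", "trial_index",
            "img1", "img2", "img3", "img4", "choice_high", "choice_low",
        ],
        "trials CSV",
    )
    ok = df["choice_high"].notna() & df["choice_low"].notna()
    out = df[ok].reset_index(drop=True)
    out.attrs["n_dropped_missing_choice"] = int((~ok).sum())
    return out
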