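"""LabelMe-style polygon annotations, rasterization, and patient-level splits.

Coordinates follow the LabelMe JSON convention: 0-based, ``x`` = column,
``y`` = row.  Rasterization fills polygons by the even-odd rule evaluated at
integer pixel centers, with pixels whose center lies exactly on a polygon
edge included (inclusive fill) — stated explicitly so overlap metrics and
area ratios computed from these masks are bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import AnnotationError, ConfigurationError
from .phantom import TUMOR, UTERUS

KNOWN_LABELS = ("uterus", "tumor")
_LABEL_CODE = {"uterus": UTERUS, "tumor": TUMOR}


@dataclass(frozen=True)
class PolygonAnnotation:
    label: str
    vertices: tuple[tuple[float, float], ...]  # (x=column, y=row), 0-based

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise AnnotationError(
                f"polygon '{self.label}' needs >= 3 vertices, got {len(self.vertices)}"
            )
        if self.label not in KNOWN_LABELS:
            raise AnnotationError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class ParseResult:
    annotations: tuple[PolygonAnnotation, ...]
    excluded: tuple[tuple[int, str], ...]  # (shape index, label) of skipped shapes
    image_shape: tuple[int, int] | None    # (rows, cols) if the document carries it


def parse_labelme(document: dict | str | Path) -> ParseResult:
    """Parse a LabelMe JSON document (dict, JSON string, or file path).

    Polygons with labels other than uterus/tumor are excluded but reported in
    the result's ``excluded`` metadata (and via a warning), never silently
    dropped.
    """
    if isinstance(document, (str, Path)):
        p = Path(document)
        if p.exists():
            document = json.loads(p.read_text())
        else:
            document = json.loads(str(document))
    if not isinstance(document, dict) or "shapes" not in document:
        raise AnnotationError("document has no 'shapes' list")
    shape = None
    if "imageHeight" in document and "imageWidth" in document:
        shape = (int(document["imageHeight"]), int(document["imageWidth"]))
    annotations: list[PolygonAnnotation] = []
    excluded: list[tuple[int, str]] = []
    for i, item in enumerate(document["shapes"]):
        try:
            label = item["label"]
            points = item["points"]
        except (TypeError, KeyError) as err:
            raise AnnotationError(f"shape {i} is malformed: missing {err}") from err
        if label not in KNOWN_LABELS:
            warnings.warn(f"shape {i}: unknown label {label!r} excluded", stacklevel=2)
            excluded.append((i, str(label)))
            continue
        try:
            vertices = tuple((float(x), float(y)) for x, y in points)
        except (TypeError, ValueError) as err:
            raise AnnotationError(f"shape {i} has malformed points") from err
        annotations.append(PolygonAnnotation(label, vertices))
    return ParseResult(tuple(annotations), tuple(excluded), shape)


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray,
                       verts: np.ndarray) -> np.ndarray:
    """Even-odd crossing test plus explicit on-edge inclusion, vectorized."""
    n = len(verts)
    inside = np.zeros(xs.shape, dtype=bool)
    on_edge = np.zeros(xs.shape, dtype=bool)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-segment: collinear and within the bounding box
        cross = (x2 - x1) * (ys - y1) - (y2 - y1) * (xs - x1)
        within = (
            (np.minimum(x1, x2) - 1e-9 <= xs) & (xs <= np.maximum(x1, x2) + 1e-9)
            & (np.minimum(y1, y2) - 1e-9 <= ys) & (ys <= np.maximum(y1, y2) + 1e-9)
        )
        on_edge |= (np.abs(cross) <= 1e-9 * max(1.0, abs(x2 - x1) + abs(y2 - y1))) & within
        # even-odd ray crossing (ray towards +x)
        crosses = (y1 > ys) != (y2 > ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < x_at)
    return inside | on_edge


def rasterize(annotations: Sequence[PolygonAnnotation],
              shape: tuple[int, int]) -> np.ndarray:
    """Fill polygons into a label mask of ``shape`` (rows, cols).

    Tumor polygons are painted after uterus polygons, so the tumor takes
    precedence where it is nested inside the organ outline.
    """
    rows, cols = shape
    mask = np.zeros((rows, cols), dtype=np.uint8)
    for ann in annotations:
        for x, y in ann.vertices:
            if not (0 <= x < cols and 0 <= y < rows):
                raise AnnotationError(
                    f"polygon '{ann.label}' vertex ({x}, {y}) outside [0, {cols}) x [0, {rows})"
                )
    yy, xx = np.mgrid[0:rows, 0:cols]
    for label in ("uterus", "tumor"):  # painting order: tumor last, wins
        for ann in annotations:
            if ann.label != label:
                continue
            verts = np.asarray(ann.vertices, dtype=np.float64)
            lo_x, lo_y = np.floor(verts.min(axis=0)).astype(int)
            hi_x, hi_y = np.ceil(verts.max(axis=0)).astype(int)
            sub = (slice(max(lo_y, 0), min(hi_y, rows - 1) + 1),
                   slice(max(lo_x, 0), min(hi_x, cols - 1) + 1))
            hit = _points_in_polygon(xx[sub].astype(float), yy[sub].astype(float), verts)
            mask[sub][hit] = _LABEL_CODE[label]
    return mask


@dataclass(frozen=True)
class DatasetSplit:
    train: tuple[str, ...]
    validation: tuple[str, ...]
    test: tuple[str, ...]

    def partition_of(self, patient_id: str) -> str:
        for name in ("train", "validation", "test"):
            if patient_id in getattr(self, name):
                return name
        raise KeyError(patient_id)

    def to_json(self) -> str:
        return json.dumps({"train": list(self.train),
                           "validation": list(self.validation),
                           "test": list(self.test)}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DatasetSplit":
        d = json.loads(text)
        return cls(tuple(d["train"]), tuple(d["validation"]), tuple(d["test"]))


def largest_remainder(total: int, ratios: Sequence[float]) -> list[int]:
    """Apportion ``total`` into integer parts proportional to ``ratios``."""
    if total < 0 or any(r < 0 for r in ratios) or sum(ratios) == 0:
        raise ConfigurationError(f"invalid apportionment: total={total}, ratios={ratios}")
    quotas = [total * r / sum(ratios) for r in ratios]
    parts = [int(np.floor(q)) for q in quotas]
    remainders = [q - p for q, p in zip(quotas, parts)]
    for i in sorted(range(len(ratios)), key=lambda i: -remainders[i])[: total - sum(parts)]:
        parts[i] += 1
    return parts


def split_dataset(patient_ids: Sequence[str], ratios: Sequence[float] = (6, 1, 3),
                  seed: int = 0) -> DatasetSplit:
    """Patient-level train/validation/test split in the given ratio.

    Sizes follow largest-remainder apportionment (117 patients at 6:1:3 gives
    70/12/35); all slices of one patient land in one partition by construction.
    """
    ids = list(patient_ids)
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate patient ids")
    n_parts = sum(1 for r in ratios if r > 0)
    if len(ids) < n_parts:
        raise ConfigurationError(
            f"need at least {n_parts} patients for ratios {tuple(ratios)}, got {len(ids)}"
        )
    if len(ratios) != 3:
        raise ConfigurationError("ratios must have three entries (train, validation, test)")
    sizes = largest_remainder(len(ids), ratios)
    order = np.random.default_rng(seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return DatasetSplit(tuple(shuffled[:a]), tuple(shuffled[a:b]), tuple(shuffled[b:]))
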