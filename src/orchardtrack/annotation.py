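"""Polygon annotation I/O, polygon/mask conversion, and image tiling.

Conventions used throughout the package:

* pixel indices are 0-based, origin at the top-left, ``x`` rightward
  (columns) and ``y`` downward (rows);
* boxes are half-open ``[x_min, x_max) x [y_min, y_max)``;
* a pixel ``(row r, col c)`` is covered by a polygon iff its *center*
  ``(c + 0.5, r + 0.5)`` lies inside under the even-odd rule.

The VIA reader/writer speaks the VGG Image Annotator 2.x region schema
(polygon regions with ``all_points_x`` / ``all_points_y``), accepting both
bare image-metadata dictionaries and full project files.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
from skimage import measure

logger = logging.getLogger(__name__)

__all__ = [
    "PolygonAnnotation",
    "TileLayout",
    "read_via",
    "write_via",
    "polygon_to_mask",
    "mask_to_polygon",
    "make_tile_layout",
    "tile_image",
    "PAPER11_SOURCE_SIZE",
    "DEFAULT_TILE_SIZE",
]

PAPER11_SOURCE_SIZE = (5184, 3456)  # (width, height)
DEFAULT_TILE_SIZE = (1088, 1088)


@dataclass
class PolygonAnnotation:
    """One polygon region attached to a named image."""

    image_name: str
    vertices: list[tuple[float, float]]
    attributes: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]
        if len(self.vertices) < 3:
            raise ValueError(
                f"polygon for {self.image_name!r} needs >=3 vertices, "
                f"got {len(self.vertices)}"
            )


@dataclass(frozen=True)
class TileLayout:
    """Tile size plus the ordered top-left origins of every tile."""

    tile_size: tuple[int, int]          # (width, height)
    origins: tuple[tuple[int, int], ...]  # (x, y) top-left per tile
    source_size: tuple[int, int]        # (width, height)

    def __post_init__(self) -> None:
        tw, th = self.tile_size
        sw, sh = self.source_size
        if tw > sw or th > sh:
            raise ValueError(
                f"tile {self.tile_size} larger than source {self.source_size}"
            )
        if len(set(self.origins)) != len(self.origins):
            raise ValueError("tile origins must be unique")
        for x, y in self.origins:
            if x < 0 or y < 0 or x + tw > sw or y + th > sh:
                raise ValueError(f"tile at ({x}, {y}) exceeds source bounds")


# ---------------------------------------------------------------------------
# VIA JSON
# ---------------------------------------------------------------------------

def _via_image_metadata(document: dict) -> dict:
    if "_via_img_metadata" in document:
        meta = document["_via_img_metadata"]
        if not isinstance(meta, dict):
            raise ValueError("malformed VIA document: '_via_img_metadata' is not an object")
        return meta
    return document


def read_via(document: dict | str) -> list[PolygonAnnotation]:
    """Parse VIA project JSON into polygon annotations.

    Accepts a parsed dict, a JSON string, or a path-like string ending in
    ``.json``. Non-polygon regions are skipped with a warning.
    """
    if isinstance(document, str):
        if document.lstrip().startswith("{"):
            document = json.loads(document)
        else:
            with open(document) as fh:
                document = json.load(fh)
    if not isinstance(document, dict):
        raise ValueError("malformed VIA document: top level is not an object")

    annotations: list[PolygonAnnotation] = []
    for key, entry in _via_image_metadata(document).items():
        if key.startswith("_via"):
            continue
        if not isinstance(entry, dict):
            raise ValueError(f"malformed VIA document: entry {key!r} is not an object")
        filename = entry.get("filename")
        if filename is None:
            raise ValueError(f"malformed VIA document: entry {key!r} missing 'filename'")
        for region in entry.get("regions", []):
            shape = region.get("shape_attributes", {})
            name = shape.get("name")
            if name not in ("polygon", "polyline"):
                logger.warning(
                    "skipping non-polygon region (shape %r) in image %s", name, filename
                )
                continue
            try:
                xs = shape["all_points_x"]
                ys = shape["all_points_y"]
            except KeyError as exc:
                raise ValueError(
                    f"malformed VIA document: region in {filename!r} missing {exc}"
                ) from None
            if len(xs) != len(ys):
                raise ValueError(
                    f"malformed VIA document: all_points_x/all_points_y length "
                    f"mismatch in {filename!r}"
                )
            annotations.append(
                PolygonAnnotation(
                    image_name=filename,
                    vertices=list(zip(xs, ys)),
                    attributes=dict(region.get("region_attributes", {})),
                )
            )
    return annotations


def write_via(annotations: Iterable[PolygonAnnotation]) -> dict:
    """Inverse of :func:`read_via`: build a VIA image-metadata document."""
    metadata: dict[str, dict] = {}
    for ann in annotations:
        key = ann.image_name
        entry = metadata.setdefault(
            key, {"filename": ann.image_name, "size": -1, "regions": [], "file_attributes": {}}
        )
        xs = [v[0] for v in ann.vertices]
        ys = [v[1] for v in ann.vertices]
        # keep integral vertices as ints so round-trips are textually stable
        if all(float(v).is_integer() for v in xs + ys):
            xs = [int(v) for v in xs]
            ys = [int(v) for v in ys]
        entry["regions"].append(
            {
                "shape_attributes": {
                    "name": "polygon",
                    "all_points_x": xs,
                    "all_points_y": ys,
                },
                "region_attributes": dict(ann.attributes),
            }
        )
    return {"_via_img_metadata": metadata}


# ---------------------------------------------------------------------------
# polygon <-> mask
# ---------------------------------------------------------------------------

def polygon_to_mask(
    polygon: PolygonAnnotation | Sequence[tuple[float, float]],
    image_size: tuple[int, int],
) -> np.ndarray:
    """Rasterize a polygon to a boolean mask (pixel-center, even-odd rule).

    Parameters
    ----------
    polygon : annotation or vertex sequence
        Vertices in ``(x, y)`` pixel coordinates.
    image_size : (height, width)
        Raster dimensions of the output mask.
    """
    if isinstance(polygon, PolygonAnnotation):
        vertices = polygon.vertices
    else:
        vertices = [(float(x), float(y)) for x, y in polygon]
    h, w = image_size
    mask = np.zeros((h, w), dtype=bool)
    if len(vertices) < 3:
        warnings.warn("degenerate polygon (<3 vertices): empty mask", stacklevel=2)
        return mask

    vx = np.array([v[0] for v in vertices])
    vy = np.array([v[1] for v in vertices])
    yc = np.arange(h) + 0.5
    xc = np.arange(w) + 0.5
    crossings = np.zeros((h, w), dtype=np.int64)
    x1, y1 = vx, vy
    x2, y2 = np.roll(vx, -1), np.roll(vy, -1)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edge never crosses a scanline
        lo, hi = (ey1, ey2) if ey1 < ey2 else (ey2, ey1)
        rows = np.nonzero((yc >= lo) & (yc < hi))[0]
        if rows.size == 0:
            continue
        x_int = ex1 + (yc[rows] - ey1) * (ex2 - ex1) / (ey2 - ey1)
        crossings[rows] += xc[None, :] < x_int[:, None]
    np.not_equal(crossings % 2, 0, out=mask)
    if not mask.any() and _polygon_area(vx, vy) == 0.0:
        warnings.warn("zero-area polygon: empty mask", stacklevel=2)
    return mask


def _polygon_area(vx: np.ndarray, vy: np.ndarray) -> float:
    return 0.5 * abs(np.sum(vx * np.roll(vy, -1) - np.roll(vx, -1) * vy))


def mask_to_polygon(mask: np.ndarray) -> list[tuple[float, float]]:
    """Trace the outer boundary of the largest connected component.

    The returned polygon re-rasterizes to the traced component under
    :func:`polygon_to_mask` (idempotent round trip for hole-free
    components).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    labels = measure.label(mask, connectivity=1)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    padded = np.pad(mask, 1).astype(float)
    contours = measure.find_contours(padded, 0.5, fully_connected="low")
    contour = max(contours, key=len)
    # find_contours works in (row, col) index space where the pixel center is
    # at integer coordinates; shift into our center-at-+0.5 convention.
    return [(float(c) - 0.5, float(r) - 0.5) for r, c in contour]


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def _paper11_origins() -> tuple[tuple[int, int], ...]:
    # 4 columns x 3 rows clamped inside a 5184x3456 frame, minus the
    # bottom-right tile: 11 tiles total. Only the count is contractual;
    # the offsets are a deterministic choice.
    cols = (0, 1365, 2731, 4096)
    rows = (0, 1184, 2368)
    origins = [(x, y) for y in rows for x in cols]
    origins.remove((4096, 2368))
    return tuple(origins)


def make_tile_layout(
    source_size: tuple[int, int],
    tile_size: tuple[int, int] = DEFAULT_TILE_SIZE,
    layout: str = "paper11",
) -> TileLayout:
    """Build the tile layout for a source image.

    ``layout="paper11"`` reproduces the 11-section split for 5184x3456
    sources with 1088x1088 tiles; any other source/tile combination falls
    back to a non-overlapping grid with edge-clamped final row/column
    (``layout="grid"`` forces the grid everywhere).
    """
    sw, sh = source_size
    tw, th = tile_size
    if tw > sw or th > sh:
        raise ValueError(f"tile {tile_size} larger than source {source_size}")
    if (
        layout == "paper11"
        and (sw, sh) == PAPER11_SOURCE_SIZE
        and (tw, th) == DEFAULT_TILE_SIZE
    ):
        return TileLayout(tile_size=(tw, th), origins=_paper11_origins(), source_size=(sw, sh))
    if layout not in ("paper11", "grid"):
        raise ValueError(f"unknown layout {layout!r}")
    xs = sorted({min(x, sw - tw) for x in range(0, sw, tw)})
    ys = sorted({min(y, sh - th) for y in range(0, sh, th)})
    origins = tuple((x, y) for y in ys for x in xs)
    return TileLayout(tile_size=(tw, th), origins=origins, source_size=(sw, sh))


def tile_image(
    image: np.ndarray,
    layout: TileLayout | None = None,
    tile_size: tuple[int, int] = DEFAULT_TILE_SIZE,
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Split an image into tiles, returning ``(tile, (x, y) origin)`` pairs."""
    h, w = image.shape[:2]
    if layout is None:
        layout = make_tile_layout((w, h), tile_size)
    if layout.source_size != (w, h):
        raise ValueError(
            f"layout is for source {layout.source_size}, image is {(w, h)}"
        )
    tw, th = layout.tile_size
    return [
        (image[y : y + th, x : x + tw], (x, y)) for x, y in layout.origins
    ]
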