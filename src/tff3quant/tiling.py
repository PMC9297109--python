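"""Annotation-driven and whole-slide tile sampling.

A whole-slide image is broken into fixed-size square tiles (default 400 px
edge).  Training tiles are sampled from pathologist polygon annotations:
an axis-aligned bounding box is placed around each annotation, as many
non-overlapping grid tiles as fit are extracted from the box, and only
tiles with at least a configurable fraction of their area (default 66%)
inside the annotation polygon are kept.  At inference time the same grid
runs over the full slide so a classifier can count positives.

Conventions: pixel coordinates are 0-based; rectangles and tiles are
half-open ``[x0, x1) x [y0, y1)``, which makes area arithmetic exact.  A
pixel ``(row i, col j)`` belongs to a polygon iff its centre
``(j + 0.5, i + 0.5)`` is covered by the polygon.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon, box
from shapely.validation import explain_validity
import shapely

logger = logging.getLogger(__name__)

__all__ = [
    "TilingConfig",
    "Rect",
    "Tile",
    "TileSet",
    "Annotation",
    "AnnotatedSlide",
    "bounding_box",
    "grid_tiles",
    "overlap_fraction",
    "sample_annotation_tiles",
    "grid_tile_slide",
    "rasterize_polygon",
    "write_tileset_tsv",
    "read_tileset_tsv",
    "write_annotations_geojson",
    "read_annotations_geojson",
    "write_slide_png",
    "read_slide_png",
]

LABEL_TFF3 = "tff3_positive"
LABEL_GASTRIC = "gastric"


@dataclass(frozen=True)
class TilingConfig:
    """Tile geometry and the annotation-overlap retention rule.

    ``microns_per_pixel`` is carried for provenance only; no computation
    here depends on physical scale.
    """

    tile_edge_px: int = 400
    min_overlap_fraction: float = 0.66
    microns_per_pixel: float = 0.25

    def __post_init__(self) -> None:
        if self.tile_edge_px < 1:
            raise ValueError(f"tile_edge_px must be >= 1, got {self.tile_edge_px}")
        if not (0 < self.min_overlap_fraction <= 1):
            raise ValueError(
                f"min_overlap_fraction must be in (0, 1], got {self.min_overlap_fraction}"
            )
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")


@dataclass(frozen=True)
class Rect:
    """Half-open axis-aligned rectangle [x0,x1) x [y0,y1) in pixels."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate Rect({self.x0},{self.y0},{self.x1},{self.y1})")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0


@dataclass(frozen=True)
class Tile:
    """One square tile: origin (x0, y0) plus edge length in pixels."""

    x0: int
    y0: int
    edge_px: int
    source_annotation: Optional[str] = None
    label: Optional[str] = None

    def as_polygon(self) -> Polygon:
        e = self.edge_px
        return box(self.x0, self.y0, self.x0 + e, self.y0 + e)


@dataclass
class TileSet:
    tiles: list[Tile]
    tile_edge_px: int

    def __len__(self) -> int:
        return len(self.tiles)

    def origins(self) -> set[tuple[int, int]]:
        return {(t.x0, t.y0) for t in self.tiles}


@dataclass
class Annotation:
    """A labelled polygon in slide pixel coordinates."""

    annotation_id: str
    label: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not isinstance(self.polygon, Polygon):
            self.polygon = Polygon(self.polygon)


@dataclass
class AnnotatedSlide:
    """RGB raster with polygon annotations and an optional label mask.

    ``mask`` uses 0 = background, 1 = TFF3-positive, 2 = gastric, matching
    the annotation labels; when present it must have the raster's shape.
    """

    raster: np.ndarray  # (H, W, 3) uint8
    annotations: list[Annotation] = field(default_factory=list)
    mask: Optional[np.ndarray] = None

    MASK_BACKGROUND = 0
    MASK_TFF3 = 1
    MASK_GASTRIC = 2

    def __post_init__(self) -> None:
        if self.raster.ndim != 3 or self.raster.shape[2] != 3:
            raise ValueError(f"raster must be (H, W, 3), got shape {self.raster.shape}")
        if self.mask is not None and self.mask.shape != self.raster.shape[:2]:
            raise ValueError("mask shape must match raster")

    @property
    def height(self) -> int:
        return self.raster.shape[0]

    @property
    def width(self) -> int:
        return self.raster.shape[1]


# ---------------------------------------------------------------------------
# Core geometry


def bounding_box(polygon: Polygon | Sequence[tuple[float, float]]) -> Rect:
    """Minimal integer-aligned half-open rectangle containing the polygon.

    Lower bounds are floored, upper bounds are ceiled, so every vertex lies
    inside the returned rectangle.  A zero-area polygon is flagged with a
    warning but still yields its (possibly 1-px wide) box.
    """
    poly = polygon if isinstance(polygon, Polygon) else Polygon(polygon)
    if len(poly.exterior.coords) < 4:  # shapely closes the ring; 3 vertices -> 4 coords
        raise ValueError("polygon needs at least 3 vertices")
    if not np.all(np.isfinite(np.asarray(poly.exterior.coords))):
        raise ValueError("polygon has non-finite coordinates")
    if poly.area == 0:
        logger.warning("degenerate polygon with zero area at %s", poly.bounds)
    minx, miny, maxx, maxy = poly.bounds
    x0, y0 = math.floor(minx), math.floor(miny)
    x1, y1 = max(math.ceil(maxx), x0 + 1), max(math.ceil(maxy), y0 + 1)
    return Rect(x0, y0, x1, y1)


def grid_tiles(rect: Rect, config: TilingConfig) -> list[Tile]:
    """Row-major non-overlapping tile grid anchored at the rect's top-left.

    Partial tiles at the right/bottom edges are discarded, never padded, so
    the count is ``floor(width/edge) * floor(height/edge)``.
    """
    e = config.tile_edge_px
    nx = rect.width // e
    ny = rect.height // e
    return [
        Tile(rect.x0 + ix * e, rect.y0 + iy * e, e)
        for iy in range(ny)
        for ix in range(nx)
    ]


def overlap_fraction(tile: Tile, polygon: Polygon) -> float:
    """Fraction of the tile's area covered by the polygon (exact clipping)."""
    if not polygon.is_valid:
        raise ValueError(f"invalid polygon: {explain_validity(polygon)}")
    tile_poly = tile.as_polygon()
    inter = tile_poly.intersection(polygon)
    return inter.area / tile_poly.area


def sample_annotation_tiles(slide: AnnotatedSlide, config: TilingConfig) -> TileSet:
    """The training-tile sampler: bounding box, grid, overlap filter.

    For each annotation a bounding box is drawn, grid tiles extracted, and
    tiles with overlap fraction >= ``config.min_overlap_fraction`` kept,
    carrying the source annotation id.  Annotations extending outside the
    raster are skipped with a warning.  Tiles retained by several
    annotations are deduplicated by origin (first annotation wins), so
    counts are per unique tile.
    """
    kept: dict[tuple[int, int], Tile] = {}
    for ann in slide.annotations:
        minx, miny, maxx, maxy = ann.polygon.bounds
        if minx < 0 or miny < 0 or maxx > slide.width or maxy > slide.height:
            logger.warning(
                "annotation %s outside raster bounds %dx%d; skipped",
                ann.annotation_id, slide.width, slide.height,
            )
            continue
        rect = bounding_box(ann.polygon)  # in-bounds: polygon passed the check above
        for tile in grid_tiles(rect, config):
            if overlap_fraction(tile, ann.polygon) >= config.min_overlap_fraction:
                origin = (tile.x0, tile.y0)
                if origin not in kept:
                    kept[origin] = Tile(
                        tile.x0, tile.y0, tile.edge_px,
                        source_annotation=ann.annotation_id,
                        label="positive" if ann.label == LABEL_TFF3 else "negative",
                    )
    return TileSet(list(kept.values()), config.tile_edge_px)


def grid_tile_slide(slide: AnnotatedSlide, config: TilingConfig) -> TileSet:
    """Full-slide inference grid: tiles over Rect(0, 0, W, H)."""
    rect = Rect(0, 0, slide.width, slide.height)
    return TileSet(grid_tiles(rect, config), config.tile_edge_px)


def rasterize_polygon(polygon: Polygon, width: int, height: int) -> np.ndarray:
    """Boolean mask of pixels whose centres are covered by the polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    j0, j1 = max(0, math.floor(minx)), min(width, math.ceil(maxx))
    i0, i1 = max(0, math.floor(miny)), min(height, math.ceil(maxy))
    mask = np.zeros((height, width), dtype=bool)
    if j1 <= j0 or i1 <= i0:
        return mask
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    inside = shapely.contains_xy(polygon, jj + 0.5, ii + 0.5)
    mask[i0:i1, j0:j1] = inside.reshape(i1 - i0, j1 - j0)
    return mask


# ---------------------------------------------------------------------------
# I/O: GeoJSON annotations, PNG rasters, TSV tile sets


def write_annotations_geojson(annotations: Sequence[Annotation], path) -> None:
    features = []
    for ann in annotations:
        features.append(
            {
                "type": "Feature",
                "properties": {"id": ann.annotation_id, "label": ann.label},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[list(pt) for pt in ann.polygon.exterior.coords]],
                },
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_annotations_geojson(path) -> list[Annotation]:
    with open(path) as fh:
        data = json.load(fh)
    anns = []
    for feat in data["features"]:
        props = feat.get("properties", {})
        ring = feat["geometry"]["coordinates"][0]
        anns.append(Annotation(str(props.get("id")), props.get("label"), Polygon(ring)))
    return anns


def write_slide_png(slide: AnnotatedSlide, path) -> None:
    from PIL import Image

    Image.fromarray(slide.raster, mode="RGB").save(path, format="PNG")


def read_slide_png(path, annotations: Optional[Sequence[Annotation]] = None) -> AnnotatedSlide:
    from PIL import Image

    raster = np.asarray(Image.open(path).convert("RGB"))
    return AnnotatedSlide(raster, list(annotations) if annotations else [])


_TSV_HEADER = "x0\ty0\tedge_px\tsource_annotation\tlabel"


def write_tileset_tsv(tileset: TileSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER + "\n")
        for t in tileset.tiles:
            fh.write(
                f"{t.x0}\t{t.y0}\t{t.edge_px}\t{t.source_annotation or ''}\t{t.label or ''}\n"
            )


def read_tileset_tsv(path) -> TileSet:
    tiles = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _TSV_HEADER:
            raise ValueError(f"unrecognised tile set header: {header!r}")
        for line in fh:
            x0, y0, edge, src, label = line.rstrip("\n").split("\t")
            tiles.append(Tile(int(x0), int(y0), int(edge), src or None, label or None))
    edge_px = tiles[0].edge_px if tiles else 0
    return TileSet(tiles, edge_px)
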