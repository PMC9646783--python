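"""Slide-to-tile conversion.

An annotated slide is cut into non-overlapping square tiles on a grid
anchored at the top-left of the ROI bounding box, enumerated row-major
(left-to-right, top-to-bottom) with 1-based consecutive indices. A tile is
retained iff the fraction of its pixels falling inside the ROI polygons
(center-of-pixel rule) reaches ``min_tissue_fraction``; partial tiles at the
right/bottom border are dropped. The row-major index order is the tile order
consumed by the 1-D average pooling downstream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from shapely import contains_xy
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .synthetic_data import SlideRecord

__all__ = ["Tile", "TileSet", "tile_slide", "export_tiles", "tile_pixels"]

SIDECAR_COLUMNS = ["file", "index", "grid_row", "grid_col", "x0", "y0",
                   "tissue_fraction"]


@dataclass(frozen=True)
class Tile:
    index: int            # 1-based, consecutive in export order
    grid_row: int
    grid_col: int
    x0: int               # half-open pixel bbox [x0, x0+size) x [y0, y0+size)
    y0: int
    tissue_fraction: float
    path: str | None = None


@dataclass
class TileSet:
    """Ordered tiles of one slide (keeps a reference to the source raster)."""

    patient_id: str
    marker: str
    tile_size: int
    tiles: list[Tile] = field(default_factory=list)
    slide: SlideRecord | None = None

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self):
        return iter(self.tiles)


def tile_pixels(tileset: TileSet, tile: Tile) -> np.ndarray:
    """Crop of the source raster for one tile."""
    if tileset.slide is None:
        raise ValueError("TileSet carries no source slide raster")
    s = tileset.tile_size
    return tileset.slide.raster[tile.y0:tile.y0 + s, tile.x0:tile.x0 + s]


def _roi_mask(polys: list[Polygon], x0: int, y0: int, w: int, h: int) -> np.ndarray:
    """Boolean in-ROI mask over a pixel window, center-of-pixel inclusion."""
    union = unary_union(polys)
    xs = np.arange(x0, x0 + w) + 0.5
    ys = np.arange(y0, y0 + h) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    return contains_xy(union, gx.ravel(), gy.ravel()).reshape(h, w)


def tile_slide(slide: SlideRecord, tile_size: int = 512,
               min_tissue_fraction: float = 0.5) -> TileSet:
    """Cut a slide into its ordered, ROI-filtered tile grid.

    An ROI smaller than one tile yields an empty TileSet; an ROI extending
    beyond the raster is an error.
    """
    if tile_size < 32:
        raise ValueError("tile_size must be >= 32")
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must lie in [0, 1]")
    ts = TileSet(patient_id=slide.patient_id, marker=str(getattr(slide.marker, "value", slide.marker)),
                 tile_size=tile_size, slide=slide)
    if not slide.roi:
        return ts
    minx, miny, maxx, maxy = unary_union(slide.roi).bounds
    if minx < 0 or miny < 0 or maxx > slide.width or maxy > slide.height:
        raise ValueError("ROI extends outside the raster bounds")
    x_anchor, y_anchor = int(np.floor(minx)), int(np.floor(miny))
    n_cols = int(np.floor((maxx - x_anchor) / tile_size))
    n_rows = int(np.floor((maxy - y_anchor) / tile_size))
    if n_cols < 1 or n_rows < 1:
        return ts

    mask = _roi_mask(slide.roi, x_anchor, y_anchor,
                     n_cols * tile_size, n_rows * tile_size)
    index = 0
    for r in range(n_rows):
        for c in range(n_cols):
            frac = float(mask[r * tile_size:(r + 1) * tile_size,
                              c * tile_size:(c + 1) * tile_size].mean())
            if frac >= min_tissue_fraction:
                index += 1
                ts.tiles.append(Tile(index=index, grid_row=r, grid_col=c,
                                     x0=x_anchor + c * tile_size,
                                     y0=y_anchor + r * tile_size,
                                     tissue_fraction=frac))
    return ts


def export_tiles(tileset: TileSet, out_dir, fmt: str = "jpeg",
                 quality: int = 90) -> list[Path]:
    """Write one image per tile plus a sidecar CSV mapping files to the grid.

    Files are named ``<patient_id>_<marker>_tile_<index>`` with a
    zero-padded 6-digit index; re-export with identical inputs is
    byte-identical. JPEG export is lossy (quality configurable); PNG is exact.
    """
    fmt = fmt.lower()
    if fmt not in ("jpeg", "jpg", "png"):
        raise ValueError("format must be 'jpeg' or 'png'")
    ext = "png" if fmt == "png" else "jpg"
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as e:
        raise OSError(f"cannot write to tile directory {out}: {e}") from e

    paths = []
    rows = []
    for tile in tileset:
        name = f"{tileset.patient_id}_{tileset.marker}_tile_{tile.index:06d}.{ext}"
        path = out / name
        img = Image.fromarray(
            (tile_pixels(tileset, tile) * 255.0 + 0.5).astype(np.uint8))
        if ext == "jpg":
            img.save(path, format="JPEG", quality=quality)
        else:
            img.save(path, format="PNG")
        paths.append(path)
        rows.append({"file": name, "index": tile.index, "grid_row": tile.grid_row,
                     "grid_col": tile.grid_col, "x0": tile.x0, "y0": tile.y0,
                     "tissue_fraction": tile.tissue_fraction})
    sidecar = out / f"{tileset.patient_id}_{tileset.marker}_tiles.csv"
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(sidecar, index=False)
    return paths


def content_hash(paths: list[Path]) -> str:
    """SHA-256 over the concatenated file bytes (export determinism checks)."""
    h = hashlib.sha256()
    for p in sorted(map(str, paths)):
        h.update(Path(p).read_bytes())
    return h.hexdigest()
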