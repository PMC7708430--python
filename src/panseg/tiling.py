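"""Deterministic tile grids and overlap-averaged stitching.

Whole sections are too large to push through the network at once, so images
are decomposed into overlapping square tiles (default 512 px, stride 256),
predicted per tile, and the per-tile probability maps are stitched back by
unweighted averaging of every tile covering a pixel.

Coordinates are 0-based, row-major, with half-open pixel intervals
``[row_start, row_start + height) x [col_start, col_start + width)``.  Edge
tiles are anchored: the last tile in a row/column is shifted inward so its
far edge coincides with the image edge — no padding, no out-of-bounds reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TileSpec:
    """One tile window; ``height``/``width`` differ from the nominal tile
    size only when the image itself is smaller than a tile."""

    row_start: int
    col_start: int
    height: int
    width: int
    source_id: str = ""

    @property
    def row_stop(self) -> int:
        return self.row_start + self.height

    @property
    def col_stop(self) -> int:
        return self.col_start + self.width


@dataclass(frozen=True)
class TileGrid:
    tiles: tuple
    stride: int
    image_height: int
    image_width: int

    def __len__(self) -> int:
        return len(self.tiles)

    def cut(self, array: np.ndarray) -> list[np.ndarray]:
        """Extract tile views from an H x W (or H x W x C) array."""
        if array.shape[0] != self.image_height or array.shape[1] != self.image_width:
            raise ValueError("array shape does not match grid")
        return [
            array[t.row_start : t.row_stop, t.col_start : t.col_stop] for t in self.tiles
        ]

    def to_frame(self) -> pd.DataFrame:
        """Grid manifest (tile_id, row_start, col_start, height, width)."""
        return pd.DataFrame(
            {
                "tile_id": range(len(self.tiles)),
                "row_start": [t.row_start for t in self.tiles],
                "col_start": [t.col_start for t in self.tiles],
                "height": [t.height for t in self.tiles],
                "width": [t.width for t in self.tiles],
            }
        )


def _axis_starts(extent: int, tile: int, stride: int) -> list[int]:
    if extent <= tile:
        return [0]
    starts = list(range(0, extent - tile, stride))
    starts.append(extent - tile)  # anchored final tile
    return starts


def plan_grid(
    height: int,
    width: int,
    tile_size: int = 512,
    stride: int = 256,
    source_id: str = "",
) -> TileGrid:
    """Plan a row-major grid of overlapping tiles covering every pixel."""
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    if not (1 <= stride <= tile_size):
        raise ValueError("stride must satisfy 1 <= stride <= tile_size")
    if height < 1 or width < 1:
        raise ValueError("image extent must be positive")
    th, tw = min(tile_size, height), min(tile_size, width)
    if th < tile_size or tw < tile_size:
        logger.info(
            "image %dx%d smaller than tile %d; using a single image-sized tile axis",
            height,
            width,
            tile_size,
        )
    tiles = tuple(
        TileSpec(r, c, th, tw, source_id)
        for r in _axis_starts(height, th, stride)
        for c in _axis_starts(width, tw, stride)
    )
    return TileGrid(tiles, stride, height, width)


def stitch_mean(grid: TileGrid, tile_predictions) -> np.ndarray:
    """Average overlapping per-tile predictions into a full-size map.

    Every output pixel is the unweighted mean of all tile predictions
    covering it.  Where all contributions are identical the common value is
    returned verbatim (tracked via min/max accumulators) so that cutting a
    map into tiles and stitching it back is a bit-exact round trip; floating
    sum/count alone rounds off 1 ulp for odd coverage counts.
    """
    preds = list(tile_predictions)
    if len(preds) != len(grid.tiles):
        raise ValueError(
            f"expected {len(grid.tiles)} tile predictions, got {len(preds)}"
        )
    H, W = grid.image_height, grid.image_width
    acc = np.zeros((H, W), np.float64)
    cnt = np.zeros((H, W), np.int32)
    lo = np.full((H, W), np.inf)
    hi = np.full((H, W), -np.inf)
    for t, p in zip(grid.tiles, preds):
        p = np.asarray(p, np.float64)
        if p.shape != (t.height, t.width):
            raise ValueError(
                f"tile prediction shape {p.shape} != tile extent {(t.height, t.width)}"
            )
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("tile prediction values must lie in [0, 1]")
        sl = np.s_[t.row_start : t.row_stop, t.col_start : t.col_stop]
        acc[sl] += p
        cnt[sl] += 1
        np.minimum(lo[sl], p, out=lo[sl])
        np.maximum(hi[sl], p, out=hi[sl])
    if cnt.min() < 1:
        raise ValueError("grid does not cover every pixel")
    out = acc / cnt
    same = lo == hi
    out[same] = lo[same]
    return out
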