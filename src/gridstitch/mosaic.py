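"""Mosaic composition: paste tiles into the whole-slide frame, no blending.

Tiles are placed at their rounded global positions in row-major scan order;
in overlap regions later tiles simply overwrite earlier ones, so any residual
misalignment stays visible as a seam instead of being smoothed away.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import imageio.v3 as iio
import tifffile

from .alignment import TilePositions
from .registration import Tile

__all__ = ["MosaicResult", "compose", "write_mosaic"]


@dataclass
class MosaicResult:
    """Composed whole-slide image + the positions that produced it."""

    image: np.ndarray
    positions: TilePositions
    frame_size: Tuple[int, int]  # (height, width)


def compose(
    tiles,
    positions: TilePositions,
    max_frame_pixels: int = 2_000_000_000,
) -> MosaicResult:
    """Paste tiles at ``positions`` into a fresh frame.

    ``tiles`` is anything iterable as a grid of :class:`Tile` (a TileGrid or
    a nested list).  Sub-pixel positions are rounded to the nearest integer
    pixel; the frame is sized to just contain every tile; uncovered pixels
    are 0.  Color tiles (``tile.color``) are composed in color, otherwise the
    grayscale working copy is used.  A frame larger than ``max_frame_pixels``
    raises (runaway-transform guard).
    """
    tile_list = [t for row in getattr(tiles, "tiles", tiles) for t in row]
    if not tile_list:
        raise ValueError("no tiles to compose")
    if len(positions) != len(tile_list):
        raise ValueError(
            f"need one position per tile: {len(positions)} positions for "
            f"{len(tile_list)} tiles"
        )
    use_color = all(t.color is not None for t in tile_list)

    rounded = {}
    for t in tile_list:
        x, y = positions[(t.row, t.col)]
        rounded[(t.row, t.col)] = (int(round(x)), int(round(y)))
    if min(v[0] for v in rounded.values()) < 0 or min(v[1] for v in rounded.values()) < 0:
        raise ValueError("positions must be normalized to be nonnegative")

    h0, w0 = tile_list[0].shape
    frame_w = max(x + t.shape[1] for t, (x, y) in ((t, rounded[(t.row, t.col)]) for t in tile_list))
    frame_h = max(y + t.shape[0] for t, (x, y) in ((t, rounded[(t.row, t.col)]) for t in tile_list))
    if frame_h * frame_w > max_frame_pixels:
        raise ValueError(
            f"mosaic frame {frame_h}x{frame_w} exceeds {max_frame_pixels} pixels; "
            "positions look like a runaway transform"
        )

    ref = tile_list[0].color if use_color else tile_list[0].pixels
    shape = (frame_h, frame_w) + ref.shape[2:]
    frame = np.zeros(shape, dtype=ref.dtype)
    for t in sorted(tile_list, key=lambda t: (t.row, t.col)):  # scan order
        x, y = rounded[(t.row, t.col)]
        img = t.color if use_color else t.pixels
        frame[y: y + img.shape[0], x: x + img.shape[1]] = img
    return MosaicResult(image=frame, positions=positions, frame_size=(frame_h, frame_w))


def write_mosaic(result: MosaicResult, path, positions_path=None) -> None:
    """Write the mosaic (TIFF default, dtype preserved; PNG by extension)
    and optionally the positions CSV (columns row, col, x, y)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, result.image)
    else:
        iio.imwrite(path, result.image)
    if positions_path is not None:
        result.positions.to_csv(positions_path)
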