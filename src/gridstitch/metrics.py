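"""Objective stitching quality metrics.

Ground-truth-free: the mean RMSE of pixel intensities over the overlap
regions of grid-adjacent tile pairs at their computed global positions (a
perfectly consistent mosaic scores 0).  Ground-truth-based (synthetic data):
the centroid distance error D_err between stitched and true tile positions,
and MSE / PSNR between the stitched and source images.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .alignment import TilePositions

__all__ = [
    "MetricReport",
    "OverlapRmse",
    "overlap_rmse",
    "centroid_distance_error",
    "image_mse_psnr",
]


@dataclass
class OverlapRmse:
    """Mean overlap RMSE plus bookkeeping of excluded (non-overlapping) pairs.

    ``value`` is NaN when no adjacent pair overlaps at the computed
    positions — the signature of a badly failed stitch.
    """

    value: float
    n_pairs: int
    n_excluded: int


@dataclass
class MetricReport:
    overlap_rmse: float
    n_overlap_pairs: int = 0
    n_excluded_pairs: int = 0
    d_err: Optional[float] = None
    mse: Optional[float] = None
    psnr: Optional[float] = None
    stitching_time_s: Optional[float] = None

    def to_dict(self) -> Dict:
        return asdict(self)

    def to_json(self, path) -> None:
        d = self.to_dict()
        for k, v in d.items():
            if isinstance(v, float) and math.isinf(v):
                d[k] = "inf"
            elif isinstance(v, float) and math.isnan(v):
                d[k] = None
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _dtype_peak(arr: np.ndarray) -> float:
    if np.issubdtype(arr.dtype, np.integer):
        return float(np.iinfo(arr.dtype).max)
    return 1.0


def overlap_rmse(tiles, positions: TilePositions) -> OverlapRmse:
    """Mean intensity RMSE over the overlaps of grid-adjacent tile pairs.

    Tiles are placed at their rounded global positions; for every
    grid-adjacent pair the intersection rectangle is compared pixelwise on
    intensities normalized to [0, 1].  Pairs whose placed rectangles do not
    intersect are excluded from the mean and counted; if every pair is
    excluded the result is NaN.
    """
    grid = {(t.row, t.col): t for row in getattr(tiles, "tiles", tiles) for t in row}
    rmses = []
    n_excluded = 0
    for (r, c), tile_a in sorted(grid.items()):
        for nb in ((r, c + 1), (r + 1, c)):
            if nb not in grid:
                continue
            tile_b = grid[nb]
            ax, ay = positions[(r, c)]
            bx, by = positions[nb]
            ax, ay, bx, by = round(ax), round(ay), round(bx), round(by)
            ha, wa = tile_a.shape
            hb, wb = tile_b.shape
            x0, x1 = max(ax, bx), min(ax + wa, bx + wb)
            y0, y1 = max(ay, by), min(ay + ha, by + hb)
            if x1 <= x0 or y1 <= y0:
                n_excluded += 1
                continue
            pa = tile_a.pixels[y0 - ay: y1 - ay, x0 - ax: x1 - ax]
            pb = tile_b.pixels[y0 - by: y1 - by, x0 - bx: x1 - bx]
            ia = pa.astype(np.float64) / _dtype_peak(pa)
            ib = pb.astype(np.float64) / _dtype_peak(pb)
            rmses.append(float(np.sqrt(np.mean((ia - ib) ** 2))))
    if not rmses:
        if n_excluded:
            warnings.warn(
                "no adjacent tile pair overlaps at the computed positions; "
                "overlap RMSE undefined",
                stacklevel=2,
            )
        return OverlapRmse(value=float("nan"), n_pairs=0, n_excluded=n_excluded)
    return OverlapRmse(
        value=float(np.mean(rmses)), n_pairs=len(rmses), n_excluded=n_excluded
    )


def centroid_distance_error(
    positions: TilePositions,
    truth_positions: TilePositions,
    tile_shape: Tuple[int, int] = (0, 0),
    normalize: bool = True,
) -> float:
    """Mean Euclidean distance between stitched and true tile centroids.

    Both position sets are min-shifted to the same (0, 0) frame first unless
    ``normalize=False``.  Since all tiles share one shape, centroid distances
    equal top-left-corner distances; ``tile_shape`` is accepted for clarity.
    """
    if set(positions.positions) != set(truth_positions.positions):
        raise ValueError("stitched and ground-truth position sets differ")
    a = positions.normalized() if normalize else positions
    b = truth_positions.normalized() if normalize else truth_positions
    h, w = tile_shape
    dists = []
    for key in a.positions:
        ax, ay = a[key]
        bx, by = b[key]
        dists.append(math.hypot((ax + w / 2) - (bx + w / 2), (ay + h / 2) - (by + h / 2)))
    return float(np.mean(dists))


def image_mse_psnr(
    stitched: np.ndarray, truth: np.ndarray, peak: Optional[float] = None
) -> Tuple[float, float]:
    """MSE and PSNR (dB) between the stitched and ground-truth images.

    If the dimensions differ, both are cropped to the top-left-aligned
    common intersection with a warning (some tools pad their output with
    extra black rows/columns).  ``peak`` defaults to the dtype maximum for
    integer images and 1.0 for floats.  PSNR is +inf iff MSE is 0.
    """
    a, b = np.asarray(stitched), np.asarray(truth)
    if a.shape != b.shape:
        common = tuple(min(sa, sb) for sa, sb in zip(a.shape, b.shape))
        if len(a.shape) != len(b.shape) or any(c == 0 for c in common):
            raise ValueError(f"incompatible image shapes {a.shape} vs {b.shape}")
        warnings.warn(
            f"image shapes differ ({a.shape} vs {b.shape}); cropping to "
            f"common region {common}",
            stacklevel=2,
        )
        a = a[tuple(slice(0, c) for c in common)]
        b = b[tuple(slice(0, c) for c in common)]
    if peak is None:
        peak = _dtype_peak(a)
    mse = float(np.mean((a.astype(np.float64) - b.astype(np.float64)) ** 2))
    psnr = float("inf") if mse == 0 else 10.0 * math.log10(peak ** 2 / mse)
    return mse, psnr
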