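"""Ground-truthed synthetic tile grids for testing and benchmarking.

A source image — either a generated histology-like texture or a binary
USAF-resolution-chart-style bar pattern — is divided into an M x N grid of
tiles with a prescribed nominal overlap, emulating whole-slide acquisition.
Optional per-axis integer stage jitter, fixed-pattern multiplicative shading
(the same vignette on every tile, as in uncorrected microscope output),
additive Gaussian noise, and blanked background tiles emulate the defects of
real acquisitions.  The exact crop position of every tile is retained as
ground truth.

The texture generator does not reproduce real tissue morphology — only its
relevant statistics for feature-based stitching: dense, high-contrast,
non-repetitive blob structure on a smoothly varying background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import imageio.v3 as iio
import tifffile
from scipy import ndimage as ndi

from .alignment import TilePositions
from .registration import Tile, TileGrid

__all__ = [
    "SynthConfig",
    "generate_texture_image",
    "generate_usaf_pattern",
    "split_image_to_grid",
    "generate_grid",
    "write_grid",
]


@dataclass
class SynthConfig:
    """Synthetic acquisition protocol.

    Defaults follow the reference protocol: a 10 x 10 grid with 30% overlap
    cut from a source image, no jitter/shading/noise (ideal stage), so the
    stitched result can be compared bit-for-bit with the source.
    """

    rows: int = 10
    cols: int = 10
    overlap_fraction: float = 0.30
    tile_h: int = 200
    tile_w: int = 200
    jitter_px: int = 0  # max |uniform integer stage error| per axis
    shading: str = "none"  # none | vignette | gradient
    shading_amplitude: float = 0.0  # e.g. 0.3 = gain varies by 30% across tile
    noise_sigma: float = 0.0  # additive Gaussian, intensity units
    background_tiles: Sequence[Tuple[int, int]] = field(default_factory=tuple)
    pattern: str = "texture"  # texture | usaf
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must be in (0, 1)")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        if self.shading not in ("none", "vignette", "gradient"):
            raise ValueError(f"unknown shading model {self.shading!r}")

    @property
    def step(self) -> Tuple[int, int]:
        """Nominal stage step (dy, dx) between adjacent tiles, px."""
        return (
            round(self.tile_h * (1.0 - self.overlap_fraction)),
            round(self.tile_w * (1.0 - self.overlap_fraction)),
        )

    @property
    def required_size(self) -> Tuple[int, int]:
        dy, dx = self.step
        return (
            (self.rows - 1) * dy + self.tile_h + 2 * self.jitter_px,
            (self.cols - 1) * dx + self.tile_w + 2 * self.jitter_px,
        )


def generate_texture_image(height: int, width: int, seed: int = 0) -> np.ndarray:
    """Bright-field-histology-like random texture, uint8.

    A smooth band-limited background with densely scattered dark blobs
    ("nuclei") of varying radius and contrast, so a determinant-of-Hessian
    detector finds abundant strong keypoints even in thin strips.
    Deterministic per seed.
    """
    if height <= 0 or width <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    base = ndi.gaussian_filter(rng.normal(0.0, 1.0, (height, width)), 2.0)
    base = (base - base.min()) / max(np.ptp(base), 1e-12)
    img = 215.0 - 40.0 * base

    n_blobs = max(1, int(height * width / 90))
    ys = rng.uniform(0, height, n_blobs)
    xs = rng.uniform(0, width, n_blobs)
    radii = rng.uniform(1.3, 3.0, n_blobs)
    amps = rng.uniform(120.0, 200.0, n_blobs)
    blob = np.zeros((height, width))
    for y, x, r, a in zip(ys, xs, radii, amps):
        y0, y1 = max(0, int(y - 4 * r)), min(height, int(y + 4 * r) + 1)
        x0, x1 = max(0, int(x - 4 * r)), min(width, int(x + 4 * r) + 1)
        if y1 <= y0 or x1 <= x0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        blob[y0:y1, x0:x1] += a * np.exp(
            -(((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * r * r))
        )
    return np.clip(img - blob, 0, 255).astype(np.uint8)


def _draw_bar_group(img: np.ndarray, y: int, x: int, bar_w: int, bar_len: int) -> None:
    """One resolution-chart element: 3 horizontal + 3 vertical bars."""
    for i in range(3):
        yy = y + i * 2 * bar_w
        img[yy: yy + bar_w, x: x + bar_len] = 0
    x2 = x + bar_len + bar_w
    for i in range(3):
        xx = x2 + i * 2 * bar_w
        img[y: y + bar_len, xx: xx + bar_w] = 0


def generate_usaf_pattern(height: int, width: int) -> np.ndarray:
    """Binary resolution-test-chart-style image, values {0, 255}, uint8.

    Axis-aligned bar triplets at several scales packed in the central region,
    with wide empty margins so that tiles cut from the corners contain no
    texture at all (the hard case for feature-based registration).
    Deterministic.
    """
    if height <= 0 or width <= 0:
        raise ValueError("dimensions must be positive")
    img = np.full((height, width), 255, dtype=np.uint8)
    # pattern confined to the central ~60%: margins stay empty
    y0, y1 = int(0.20 * height), int(0.80 * height)
    x0, x1 = int(0.20 * width), int(0.80 * width)
    scales = [max(2, int(min(height, width) * f)) for f in (0.012, 0.008, 0.005, 0.003)]
    y = y0
    si = 0
    while y < y1:
        bar_w = scales[si % len(scales)]
        bar_len = 5 * bar_w
        group_h = max(5 * bar_w, bar_len)
        group_w = bar_len + bar_w + 5 * bar_w
        x = x0 + (si % 3) * (group_w // 3)  # stagger rows to break periodicity
        while x + group_w < x1:
            if y + group_h < y1:
                _draw_bar_group(img, y, x, bar_w, bar_len)
            x += group_w + 3 * bar_w
        y += group_h + 4 * bar_w
        si += 1
    return img


def _shading_field(h: int, w: int, model: str, amplitude: float) -> Optional[np.ndarray]:
    if model == "none" or amplitude == 0:
        return None
    if model == "vignette":
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        d2 = ((yy - cy) / max(cy, 1)) ** 2 + ((xx - cx) / max(cx, 1)) ** 2
        return 1.0 - amplitude * d2 / 2.0  # gain 1 at center, 1-amplitude at corner
    # linear-gradient flat-field error across x
    xx = np.linspace(0.0, 1.0, w)
    return np.tile(1.0 - amplitude * xx, (h, 1))


def split_image_to_grid(
    image: np.ndarray, config: SynthConfig
) -> Tuple[TileGrid, TilePositions]:
    """Cut an image into a ground-truthed tile grid per ``config``.

    Tile (r, c) is cropped at its nominal grid position plus independent
    integer jitter uniform in [-jitter_px, +jitter_px] per axis; the actual
    crop positions are returned as ground truth.  Shading is applied per
    tile (the same field on every tile), then noise; tiles listed in
    ``background_tiles`` are replaced by the modal background intensity.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("source image must be 2-D grayscale")
    req = config.required_size
    if image.shape[0] < req[0] or image.shape[1] < req[1]:
        raise ValueError(
            f"source image {image.shape} too small; need at least {req} for "
            f"{config.rows}x{config.cols} tiles of {config.tile_h}x{config.tile_w} "
            f"with overlap {config.overlap_fraction} and jitter {config.jitter_px}"
        )
    rng = np.random.default_rng(config.seed)
    dy, dx = config.step
    H, W = config.tile_h, config.tile_w
    margin = config.jitter_px
    gain = _shading_field(H, W, config.shading, config.shading_amplitude)
    if np.issubdtype(image.dtype, np.integer):
        lo, hi = np.iinfo(image.dtype).min, np.iinfo(image.dtype).max
        background = int(np.bincount(image.ravel() - lo).argmax()) + lo
    else:
        lo, hi = float(image.min()), float(image.max())
        background = float(np.median(image))
    bg_set = {tuple(rc) for rc in config.background_tiles}

    tiles: List[List[Tile]] = []
    truth = {}
    for r in range(config.rows):
        row = []
        for c in range(config.cols):
            jx = int(rng.integers(-margin, margin + 1)) if margin else 0
            jy = int(rng.integers(-margin, margin + 1)) if margin else 0
            x = margin + c * dx + jx
            y = margin + r * dy + jy
            truth[(r, c)] = (float(x), float(y))
            if (r, c) in bg_set:
                px = np.full((H, W), background, dtype=np.float64)
            else:
                px = image[y: y + H, x: x + W].astype(np.float64)
                if gain is not None:
                    px = px * gain
            if config.noise_sigma > 0:
                px = px + rng.normal(0.0, config.noise_sigma, px.shape)
            px = np.clip(px, lo, hi).astype(image.dtype)
            row.append(Tile(row=r, col=c, pixels=px))
        tiles.append(row)

    grid = TileGrid(tiles=tiles, overlap_fraction=config.overlap_fraction)
    positions = TilePositions(positions=truth, origin=(0, 0))
    return grid, positions


def generate_grid(
    config: SynthConfig,
) -> Tuple[TileGrid, TilePositions, np.ndarray]:
    """Generate the source image for ``config.pattern`` and split it."""
    h, w = config.required_size
    if config.pattern == "texture":
        source = generate_texture_image(h, w, seed=config.seed)
    elif config.pattern == "usaf":
        source = generate_usaf_pattern(h, w)
    else:
        raise ValueError(f"unknown pattern {config.pattern!r}")
    grid, truth = split_image_to_grid(source, config)
    return grid, truth, source


def write_grid(
    grid: TileGrid,
    truth: TilePositions,
    out_dir,
    source: Optional[np.ndarray] = None,
    fmt: str = "tif",
    pattern: str = "r{row:02d}_c{col:02d}",
) -> Path:
    """Write tiles as TIFF/PNG with row-major filenames, plus the
    ground-truth positions CSV and optionally the source image."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for row in grid.tiles:
        for t in row:
            name = pattern.format(row=t.row, col=t.col) + "." + fmt
            if fmt in ("tif", "tiff"):
                tifffile.imwrite(out / name, t.pixels)
            else:
                iio.imwrite(out / name, t.pixels)
    truth.to_csv(out / "truth_positions.csv")
    if source is not None:
        tifffile.imwrite(out / "source.tif", source)
    return out
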