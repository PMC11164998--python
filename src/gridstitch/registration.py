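"""Pairwise translation estimation between adjacent tiles.

The translation between a tile and its north/west neighbor is recovered from
blob features.  Feature extraction is restricted to a thin strip of the
nominal overlap (default 5% of the tile width/height) shared by both tiles;
when no reliable translation can be estimated there, the full nominal overlap
is used as a fallback.  The transformation model is pure translation: tiles
are acquired at fixed magnification and orientation by orthogonal stage
motion, so scale and rotation are negligible.

Feature detector
----------------
A SURF-style scale-space blob detector: the scale-normalized determinant of
the Hessian ``sigma^4 * (Dxx*Dyy - Dxy^2)`` is computed at a small set of
sigmas from Gaussian derivatives, local maxima above a response threshold are
kept, and peak locations are refined to sub-pixel precision by a quadratic
fit.  Descriptors are mean/std-normalized intensity patches sampled on a grid
scaled by the keypoint's sigma, which makes matching invariant to smooth
multiplicative shading (flat-field/vignetting) and additive offsets.  The
detector is pluggable: any callable with the same signature and "keep
strongest by response" semantics can replace :func:`detect_features`.

Robust fitting is MSAC (truncated-quadratic-loss RANSAC); a single
correspondence proposes a translation hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage.feature import peak_local_max

from .config import DetectorConfig, MsacConfig

__all__ = [
    "Tile",
    "TileGrid",
    "FeatureSet",
    "Translation",
    "PairwiseLink",
    "detect_features",
    "match_features",
    "estimate_translation_msac",
    "register_pair",
    "filter_translation",
    "translation_bounds",
]

NORTH = "north"
WEST = "west"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Tile:
    """One field of view of the grid: grayscale working copy + metadata.

    ``pixels`` is the single-channel working copy used for feature detection;
    ``color`` optionally keeps the original channels for composition.
    """

    row: int
    col: int
    pixels: np.ndarray
    color: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 3:  # RGB input: keep channels, work on luminance
            if self.color is None:
                self.color = self.pixels
            rgb = self.pixels[..., :3].astype(np.float64)
            lum = rgb @ np.array([0.2125, 0.7154, 0.0721])
            self.pixels = lum.astype(self.pixels.dtype)
        if self.pixels.ndim != 2:
            raise ValueError(f"tile pixels must be 2-D, got {self.pixels.ndim}-D")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=np.float64))):
            raise ValueError("tile intensities must be finite")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # (H, W)


@dataclass
class TileGrid:
    """The M x N tile collection plus acquisition metadata."""

    tiles: List[List[Tile]]  # [row][col]
    overlap_fraction: float
    scan_order: str = "row-major"

    def __post_init__(self) -> None:
        shapes = {t.shape for row in self.tiles for t in row}
        if len(shapes) > 1:
            raise ValueError(f"all tiles must share one shape, got {shapes}")

    @property
    def M(self) -> int:
        return len(self.tiles)

    @property
    def N(self) -> int:
        return len(self.tiles[0]) if self.tiles else 0

    @property
    def tile_shape(self) -> Tuple[int, int]:
        return self.tiles[0][0].shape

    def __getitem__(self, key: Tuple[int, int]) -> Tile:
        r, c = key
        return self.tiles[r][c]


@dataclass
class FeatureSet:
    """Keypoints (x, y sub-pixel, tile-local), scales, responses, descriptors."""

    keypoints: np.ndarray  # (n, 2) x, y
    scales: np.ndarray  # (n,)
    responses: np.ndarray  # (n,)
    descriptors: np.ndarray  # (n, d)

    def __len__(self) -> int:
        return len(self.keypoints)

    @classmethod
    def empty(cls, descriptor_dim: int = 0) -> "FeatureSet":
        return cls(
            keypoints=np.empty((0, 2)),
            scales=np.empty(0),
            responses=np.empty(0),
            descriptors=np.empty((0, descriptor_dim)),
        )


@dataclass(frozen=True)
class Translation:
    """Displacement of the moving tile's top-left corner in the reference
    tile's frame (x rightward, y downward, 0-based, sub-pixel)."""

    t_x: float = float("nan")
    t_y: float = float("nan")

    @property
    def is_finite(self) -> bool:
        return bool(np.isfinite(self.t_x) and np.isfinite(self.t_y))

    @classmethod
    def invalid(cls) -> "Translation":
        return cls()


@dataclass
class PairwiseLink:
    """A directed neighbor relation (reference -> moving) with its estimate.

    ``status == "invalid"`` always coincides with NaN translation components
    and NaN ``n_matched``; downstream code branches on ``status``, never on
    NaN arithmetic.
    """

    reference: Tuple[int, int]
    moving: Tuple[int, int]
    direction: str  # NORTH or WEST
    translation: Translation = field(default_factory=Translation.invalid)
    n_matched: float = float("nan")  # MSAC inlier count; NaN when invalid
    stage_used: Optional[str] = None  # "strip" | "full_overlap" | "repaired"
    status: str = "invalid"  # "valid" | "invalid"

    def __post_init__(self) -> None:
        rr, rc = self.reference
        mr, mc = self.moving
        if self.direction == WEST:
            if not (mr == rr and mc == rc + 1):
                raise ValueError("west link requires moving = (row, col+1)")
        elif self.direction == NORTH:
            if not (mc == rc and mr == rr + 1):
                raise ValueError("north link requires moving = (row+1, col)")
        else:
            raise ValueError(f"direction must be 'north' or 'west', got {self.direction!r}")
        if self.status == "valid" and not self.translation.is_finite:
            raise ValueError("valid link requires finite translation")

    @property
    def is_valid(self) -> bool:
        return self.status == "valid"

    def invalidated(self) -> "PairwiseLink":
        return replace(
            self,
            translation=Translation.invalid(),
            n_matched=float("nan"),
            status="invalid",
        )


# ---------------------------------------------------------------------------
# feature detection
# ---------------------------------------------------------------------------

def _quadratic_refine(resp: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    """Sub-pixel peak refinement by a separable 1-D quadratic fit per axis."""
    h, w = resp.shape
    dy = np.zeros(len(rows))
    dx = np.zeros(len(cols))
    interior_r = (rows > 0) & (rows < h - 1)
    interior_c = (cols > 0) & (cols < w - 1)
    rr, cc = rows[interior_r], cols[interior_r]
    num = resp[rr + 1, cc] - resp[rr - 1, cc]
    den = resp[rr + 1, cc] - 2.0 * resp[rr, cc] + resp[rr - 1, cc]
    with np.errstate(divide="ignore", invalid="ignore"):
        off = np.where(den != 0, -0.5 * num / den, 0.0)
    dy[interior_r] = np.clip(off, -0.5, 0.5)
    rr, cc = rows[interior_c], cols[interior_c]
    num = resp[rr, cc + 1] - resp[rr, cc - 1]
    den = resp[rr, cc + 1] - 2.0 * resp[rr, cc] + resp[rr, cc - 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        off = np.where(den != 0, -0.5 * num / den, 0.0)
    dx[interior_c] = np.clip(off, -0.5, 0.5)
    return dx, dy


def _patch_descriptors(region: np.ndarray, xs, ys, sigmas, cfg: DetectorConfig):
    """Mean/std-normalized intensity patches sampled at the keypoint scale."""
    g = cfg.descriptor_grid
    half = (g - 1) / 2.0
    offsets = np.arange(g) - half  # (g,)
    oy, ox = np.meshgrid(offsets, offsets, indexing="ij")
    descs = np.empty((len(xs), g * g))
    keep = np.ones(len(xs), dtype=bool)
    for i, (x, y, s) in enumerate(zip(xs, ys, sigmas)):
        step = cfg.descriptor_spacing * s
        coords = np.stack([y + oy.ravel() * step, x + ox.ravel() * step])
        patch = ndi.map_coordinates(region, coords, order=1, mode="reflect")
        std = patch.std()
        if std < 1e-9:
            keep[i] = False
            continue
        descs[i] = (patch - patch.mean()) / std
    return descs, keep


def detect_features(
    region: np.ndarray,
    response_threshold: float,
    region_offset: Tuple[float, float] = (0.0, 0.0),
    config: Optional[DetectorConfig] = None,
) -> FeatureSet:
    """Detect scale-space determinant-of-Hessian blobs in ``region``.

    Keypoint coordinates are shifted by ``region_offset`` (x, y) into the
    tile-local frame.  A constant or featureless region yields an empty
    :class:`FeatureSet`.  Deterministic for fixed input.
    """
    if response_threshold < 0:
        raise ValueError("response_threshold must be >= 0")
    region = np.asarray(region, dtype=np.float64)
    if region.size == 0:
        raise ValueError("region must be nonempty")
    cfg = config or DetectorConfig(response_threshold=response_threshold)
    if cfg.response_threshold != response_threshold:
        cfg = replace(cfg, response_threshold=response_threshold)

    all_x, all_y, all_s, all_r = [], [], [], []
    # strictly positive floor so flat regions yield no peaks even at threshold 0
    thr = max(cfg.response_threshold, 1e-9)
    for s in cfg.sigmas:
        dxx = ndi.gaussian_filter(region, s, order=(0, 2))
        dyy = ndi.gaussian_filter(region, s, order=(2, 0))
        dxy = ndi.gaussian_filter(region, s, order=(1, 1))
        resp = s ** 4 * (dxx * dyy - dxy ** 2)
        peaks = peak_local_max(
            resp, min_distance=cfg.min_distance, threshold_abs=thr, exclude_border=1
        )
        if len(peaks) == 0:
            continue
        rows, cols = peaks[:, 0], peaks[:, 1]
        ddx, ddy = _quadratic_refine(resp, rows, cols)
        all_x.append(cols + ddx)
        all_y.append(rows + ddy)
        all_s.append(np.full(len(rows), s))
        all_r.append(resp[rows, cols])

    if not all_x:
        return FeatureSet.empty(cfg.descriptor_grid ** 2)

    xs = np.concatenate(all_x)
    ys = np.concatenate(all_y)
    ss = np.concatenate(all_s)
    rs = np.concatenate(all_r)
    # strongest first; (y, x, sigma) breaks response ties deterministically
    order = np.lexsort((ss, xs, ys, -rs))[: cfg.max_keypoints]
    xs, ys, ss, rs = xs[order], ys[order], ss[order], rs[order]

    descs, keep = _patch_descriptors(region, xs, ys, ss, cfg)
    xs, ys, ss, rs, descs = xs[keep], ys[keep], ss[keep], rs[keep], descs[keep]

    ox, oy = region_offset
    kps = np.column_stack([xs + ox, ys + oy])
    return FeatureSet(keypoints=kps, scales=ss, responses=rs, descriptors=descs)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def match_features(
    fs_ref: FeatureSet, fs_mov: FeatureSet, ratio: float = 0.8
) -> np.ndarray:
    """Match descriptors: mutual nearest neighbor + Lowe ratio test.

    Returns an ``(n, 2, 2)`` array of correspondences
    ``[((x, y)_ref, (x, y)_mov), ...]``; each keypoint appears at most once.
    """
    if len(fs_ref) == 0 or len(fs_mov) == 0:
        return np.empty((0, 2, 2))
    d = cdist(fs_ref.descriptors, fs_mov.descriptors)
    best_mov = np.argmin(d, axis=1)
    best_ref = np.argmin(d, axis=0)
    idx_ref = np.arange(len(fs_ref))
    mutual = best_ref[best_mov] == idx_ref
    if d.shape[1] >= 2:
        part = np.partition(d, 1, axis=1)
        first, second = part[:, 0], part[:, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ok_ratio = first <= ratio * second
        ok_ratio |= second == 0  # identical duplicated descriptors
    else:
        ok_ratio = np.ones(len(fs_ref), dtype=bool)
    sel = mutual & ok_ratio
    pairs = np.stack(
        [fs_ref.keypoints[idx_ref[sel]], fs_mov.keypoints[best_mov[sel]]], axis=1
    )
    return pairs


# ---------------------------------------------------------------------------
# MSAC translation estimation
# ---------------------------------------------------------------------------

def msac_score(displacements: np.ndarray, hypothesis: np.ndarray, inlier_tol: float) -> float:
    """Truncated quadratic loss of one translation hypothesis."""
    r2 = np.sum((displacements - hypothesis) ** 2, axis=1)
    return float(np.sum(np.minimum(r2, inlier_tol ** 2)))


def estimate_translation_msac(
    correspondences: np.ndarray,
    inlier_tol: float = 2.0,
    confidence: float = 0.99,
    max_iters: int = 500,
    seed: int = 0,
    min_matches: int = 3,
    min_inliers: int = 3,
    full_output: bool = False,
) -> Optional[Tuple[Translation, int]]:
    """Fit a translation to correspondences with M-estimator sample consensus.

    Each correspondence proposes a hypothesis (its own displacement);
    hypotheses are scored by the sum of squared residuals truncated at
    ``inlier_tol**2``.  When there are no more correspondences than
    ``max_iters`` every hypothesis is scored (exhaustive, deterministic);
    otherwise hypotheses are sampled with early termination at the requested
    confidence.  The final translation is the mean displacement over the best
    hypothesis's inliers.

    Returns ``None`` ("not found") when too few correspondences or inliers —
    the caller then falls back to the full overlap region.  With
    ``full_output=True`` the winning hypothesis and its truncated-loss score
    are appended to the return tuple.
    """
    if inlier_tol <= 0:
        raise ValueError("inlier_tol must be > 0")
    corr = np.asarray(correspondences, dtype=np.float64)
    n = len(corr)
    if n < min_matches:
        return None
    disp = corr[:, 0, :] - corr[:, 1, :]  # ref - mov
    tol2 = inlier_tol ** 2

    if n <= max_iters:
        # all-pairs squared distances between displacement vectors
        d2 = cdist(disp, disp, "sqeuclidean")
        scores = np.minimum(d2, tol2).sum(axis=1)
        best = int(np.argmin(scores))  # ties -> lowest index
    else:
        rng = np.random.default_rng(seed)
        best, best_score = 0, np.inf
        n_trials = max_iters
        i = 0
        while i < n_trials:
            k = int(rng.integers(n))
            r2 = np.sum((disp - disp[k]) ** 2, axis=1)
            score = float(np.minimum(r2, tol2).sum())
            if score < best_score:
                best, best_score = k, score
                inlier_frac = float(np.mean(r2 <= tol2))
                if 0 < inlier_frac < 1:
                    need = np.log(1 - confidence) / np.log(1 - inlier_frac)
                    n_trials = min(max_iters, int(np.ceil(need)))
                elif inlier_frac >= 1:
                    break
            i += 1

    r2 = np.sum((disp - disp[best]) ** 2, axis=1)
    inliers = r2 <= tol2
    n_in = int(inliers.sum())
    if n_in < min_inliers:
        return None
    t = disp[inliers].mean(axis=0)
    translation = Translation(t_x=float(t[0]), t_y=float(t[1]))
    if full_output:
        score = float(np.minimum(r2, tol2).sum())
        return translation, n_in, disp[best].copy(), score
    return translation, n_in


# ---------------------------------------------------------------------------
# stage-model filter
# ---------------------------------------------------------------------------

def translation_bounds(
    direction: str, W: int, H: int, overlap_fraction: float, slack_fraction: float = 0.02
):
    """Mechanically plausible (t_x, t_y) intervals for a link direction.

    The stage advances by one tile minus the overlap; imperfect motors add
    uncertainty of ``slack_fraction`` (default 2%) of the tile dimension.
    """
    if direction == WEST:
        lo, hi = W * (1 - overlap_fraction) - slack_fraction * W, W * (1 - overlap_fraction) + slack_fraction * W
        return (lo, hi), (-slack_fraction * H, slack_fraction * H)
    if direction == NORTH:
        lo, hi = H * (1 - overlap_fraction) - slack_fraction * H, H * (1 - overlap_fraction) + slack_fraction * H
        return (-slack_fraction * W, slack_fraction * W), (lo, hi)
    raise ValueError(f"unknown direction {direction!r}")


def _in_bounds(t: Translation, direction, W, H, overlap_fraction, slack_fraction) -> bool:
    (x_lo, x_hi), (y_lo, y_hi) = translation_bounds(
        direction, W, H, overlap_fraction, slack_fraction
    )
    return bool(x_lo <= t.t_x <= x_hi and y_lo <= t.t_y <= y_hi)


def filter_translation(
    link: PairwiseLink,
    W: int,
    H: int,
    overlap_fraction: float,
    slack_fraction: float = 0.02,
) -> PairwiseLink:
    """Discard translations outside the stage-motion range (boundaries inclusive).

    A violating link becomes invalid with sentinel translation and match count.
    Invalid links pass through unchanged.
    """
    if not link.is_valid:
        return link
    if _in_bounds(link.translation, link.direction, W, H, overlap_fraction, slack_fraction):
        return link
    return link.invalidated()


# ---------------------------------------------------------------------------
# two-stage pairwise registration
# ---------------------------------------------------------------------------

def _stage_windows(direction: str, H: int, W: int, overlap_fraction: float,
                   strip_fraction: float, stage: str):
    """Pixel windows (ref_slice, ref_offset, mov_slice, mov_offset) per stage.

    Strip stage: the edge-most ``strip_fraction`` band of the overlap on the
    reference tile and the geometrically corresponding band on the moving
    tile, so both windows image the same physical region.  Full stage: the
    entire nominal overlap on both tiles.
    """
    if direction == WEST:
        ow = max(1, round(overlap_fraction * W))
        sw = max(1, round(strip_fraction * W))
        if stage == "strip":
            ref_sl = np.s_[:, W - sw: W]
            mov_sl = np.s_[:, ow - sw: ow]
            return ref_sl, (W - sw, 0), mov_sl, (ow - sw, 0)
        ref_sl = np.s_[:, W - ow: W]
        mov_sl = np.s_[:, 0: ow]
        return ref_sl, (W - ow, 0), mov_sl, (0, 0)
    ow = max(1, round(overlap_fraction * H))
    sh = max(1, round(strip_fraction * H))
    if stage == "strip":
        ref_sl = np.s_[H - sh: H, :]
        mov_sl = np.s_[ow - sh: ow, :]
        return ref_sl, (0, H - sh), mov_sl, (0, ow - sh)
    ref_sl = np.s_[H - ow: H, :]
    mov_sl = np.s_[0: ow, :]
    return ref_sl, (0, H - ow), mov_sl, (0, 0)


def _attempt_stage(ref, mov, direction, overlap_fraction, strip_fraction,
                   detector: DetectorConfig, msac: MsacConfig, seed, stage):
    H, W = ref.shape
    ref_sl, ref_off, mov_sl, mov_off = _stage_windows(
        direction, H, W, overlap_fraction, strip_fraction, stage
    )
    fs_ref = detect_features(
        ref.pixels[ref_sl], detector.response_threshold, ref_off, detector
    )
    fs_mov = detect_features(
        mov.pixels[mov_sl], detector.response_threshold, mov_off, detector
    )
    corr = match_features(fs_ref, fs_mov)
    return estimate_translation_msac(
        corr,
        inlier_tol=msac.inlier_tol,
        confidence=msac.confidence,
        max_iters=msac.max_iters,
        seed=seed,
        min_matches=msac.min_matches,
        min_inliers=msac.min_inliers,
    )


def register_pair(
    ref: Tile,
    mov: Tile,
    direction: str,
    overlap_fraction: float,
    strip_fraction: float = 0.05,
    detector: Optional[DetectorConfig] = None,
    msac: Optional[MsacConfig] = None,
    slack_fraction: float = 0.02,
    seed: int = 0,
    stages: Sequence[str] = ("strip", "full_overlap"),
) -> PairwiseLink:
    """Estimate the translation of ``mov`` relative to ``ref``.

    Stage 1 restricts detection/matching to the shared overlap strip; if the
    transformation cannot be computed there (too few matches or inliers) or
    the strip estimate falls outside the stage-motion range, stage 2 retries
    on the entire nominal overlap.  A link that fails both stages is returned
    invalid with sentinel values (the repair step fills it in later).

    ``stages`` restricts which stages run, e.g. ``("full_overlap",)``.
    """
    if ref.shape != mov.shape:
        raise ValueError(
            f"grid inconsistency: tile shapes differ {ref.shape} vs {mov.shape}"
        )
    if not (0 < strip_fraction <= overlap_fraction < 1):
        raise ValueError("require 0 < strip_fraction <= overlap_fraction < 1")
    detector = detector or DetectorConfig()
    msac = msac or MsacConfig()
    H, W = ref.shape
    link = PairwiseLink(
        reference=(ref.row, ref.col), moving=(mov.row, mov.col), direction=direction
    )

    last = None  # best-effort estimate kept if every stage is range-rejected
    for stage in stages:
        result = _attempt_stage(
            ref, mov, direction, overlap_fraction, strip_fraction,
            detector, msac, seed, stage,
        )
        if result is None:
            continue
        t, n_in = result
        last = (t, n_in, stage)
        if _in_bounds(t, direction, W, H, overlap_fraction, slack_fraction):
            return replace(
                link, translation=t, n_matched=float(n_in),
                stage_used=stage, status="valid",
            )
    if last is not None:
        # out-of-range estimate from the final stage: surface it so the
        # downstream stage-model filter records the discard
        t, n_in, stage = last
        return replace(
            link, translation=t, n_matched=float(n_in),
            stage_used=stage, status="valid",
        )
    return link
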