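"""Configuration objects shared across the stitching pipeline.

All tunables of the pipeline live here: detector and matcher settings,
robust-estimation (MSAC) parameters, and the grid/acquisition description.
Configs are plain dataclasses serializable to/from YAML key-value files;
command-line flags override file values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Tuple

import yaml

#: Hessian-determinant response thresholds per imaging modality.  High-contrast
#: bright-field tissue yields large blob responses, so a high threshold keeps
#: only dominant features; low-contrast phase-contrast and fluorescence images
#: need an essentially permissive threshold.
MODALITY_THRESHOLDS = {
    "brightfield": 1000.0,
    "phase": 1.0,
    "fluorescence": 1.0,
}

#: Scales (Gaussian sigmas, px) of the blob detector's scale space.
DEFAULT_SIGMAS = (1.2, 1.6, 2.2, 3.0)


@dataclass(frozen=True)
class DetectorConfig:
    """Settings of the determinant-of-Hessian blob detector and descriptor.

    Parameters
    ----------
    response_threshold:
        Minimum scale-normalized determinant-of-Hessian response for a
        keypoint to be retained.  Use :data:`MODALITY_THRESHOLDS` presets
        or set explicitly.
    sigmas:
        Scale-space sigmas (px) at which blobs are detected.
    min_distance:
        Minimum spacing (px) between peaks at one scale.
    max_keypoints:
        Keep at most this many strongest keypoints per region.
    descriptor_grid:
        Side length of the square sampling grid of the patch descriptor.
    descriptor_spacing:
        Sample spacing in units of the keypoint's sigma.
    """

    response_threshold: float = MODALITY_THRESHOLDS["brightfield"]
    sigmas: Tuple[float, ...] = DEFAULT_SIGMAS
    min_distance: int = 2
    max_keypoints: int = 500
    descriptor_grid: int = 9
    descriptor_spacing: float = 1.0

    @classmethod
    def for_modality(cls, modality: str, **kwargs) -> "DetectorConfig":
        try:
            thr = MODALITY_THRESHOLDS[modality]
        except KeyError:
            raise ValueError(
                f"unknown modality {modality!r}; expected one of "
                f"{sorted(MODALITY_THRESHOLDS)}"
            ) from None
        return cls(response_threshold=thr, **kwargs)


@dataclass(frozen=True)
class MsacConfig:
    """M-estimator sample consensus parameters for translation fitting.

    The translation model has two degrees of freedom, so a single
    correspondence generates a hypothesis; ``min_inliers`` of 3 guards
    against accidental single-match consensus.
    """

    inlier_tol: float = 2.0  # px
    confidence: float = 0.99
    max_iters: int = 500
    min_matches: int = 3
    min_inliers: int = 3


@dataclass
class PipelineConfig:
    """Full description of one stitching run."""

    input_dir: str = "."
    rows: int = 1
    cols: int = 1
    overlap_fraction: float = 0.25
    strip_fraction: float = 0.05
    slack_fraction: float = 0.02
    modality: Optional[str] = "brightfield"
    response_threshold: Optional[float] = None  # overrides modality preset
    graph: str = "mst"  # or "spt"
    penalty_constant: float = 1.0
    seed: int = 0
    pattern: str = "r{row:02d}_c{col:02d}"
    scan_order: str = "row-major"  # or "serpentine"
    output_dir: Optional[str] = None
    max_frame_pixels: int = 2_000_000_000

    def __post_init__(self) -> None:
        if not (0.0 < self.strip_fraction <= self.overlap_fraction < 1.0):
            raise ValueError(
                "require 0 < strip_fraction <= overlap_fraction < 1, got "
                f"strip={self.strip_fraction}, overlap={self.overlap_fraction}"
            )
        if not (0.0 <= self.slack_fraction < self.overlap_fraction):
            raise ValueError(
                "require 0 <= slack_fraction < overlap_fraction, got "
                f"slack={self.slack_fraction}, overlap={self.overlap_fraction}"
            )
        if self.graph not in ("mst", "spt"):
            raise ValueError(f"graph must be 'mst' or 'spt', got {self.graph!r}")

    def detector_config(self) -> DetectorConfig:
        if self.response_threshold is not None:
            return DetectorConfig(response_threshold=self.response_threshold)
        return DetectorConfig.for_modality(self.modality or "brightfield")

    def msac_config(self) -> MsacConfig:
        return MsacConfig()

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
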