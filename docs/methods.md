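# Methods

## Model and assumptions

Tiles are acquired on an M × N grid by orthogonal stage motion at fixed
magnification and orientation, so the transform between adjacent tiles is a
pure translation (t_x, t_y); rotation and scale are treated as exactly zero.
The nominal overlap fraction *o* is assumed known (it is required input, as
on most scanners), and stage error is assumed bounded: the true offset
between neighbors lies within the nominal offset ± `slack_fraction`
(default 2%) of the tile dimension. Everything downstream — the restricted
search strips, the validity filter, the repair averages — relies on these
assumptions; grids that violate them (rotated stages, unknown overlap,
drifting magnification) are out of scope.

## Pairwise registration

**Detector.** A SURF-style scale-space blob detector built from Gaussian
derivatives: at each sigma in `DetectorConfig.sigmas` (default 1.2, 1.6,
2.2, 3.0 px) the scale-normalized determinant of the Hessian
σ⁴(D_xx·D_yy − D_xy²) is computed and local maxima above
`response_threshold` are kept (at most `max_keypoints = 500` strongest per
region). Peak locations are refined to sub-pixel precision with a separable
1-D quadratic fit, clipped to ±0.5 px. Modality presets map to thresholds
of 1000 (bright-field, high contrast) and 1 (phase-contrast/fluorescence);
thresholds apply to 8-bit-range intensities. The detector is pluggable —
any "keep strongest by response" detector with the same signature works.

**Descriptor and matching.** Each keypoint is described by a 9 × 9 intensity
patch sampled at spacing σ (bilinear, reflected at region borders),
normalized to zero mean and unit variance. The normalization makes matching
invariant to local affine intensity changes, which is what smooth
multiplicative shading looks like at patch scale — this is the mechanism
behind the vignette robustness the tests check. Matching is mutual nearest
neighbor in Euclidean descriptor space with a 0.8 ratio test.

**Strips.** Stage 1 of the two-stage strategy restricts detection to
`strip_fraction` (default 0.05) of the tile dimension. The reference tile
contributes the edge-most strip of its overlap (e.g. its rightmost 5%
columns for a west link); the moving tile contributes the geometrically
corresponding band inside its overlap, computed from the nominal offset.
Both windows are cropped exactly, with no context padding: at zero jitter
the two crops are then pixel-identical, the detector (deterministic) finds
identical sub-pixel keypoints in both, and every inlier displacement is an
exact integer — which is what makes the clean-grid mosaic reproduce the
source bit for bit. Under jitter the windows overlap partially; the shared
band shrinks by the relative jitter, so the strip must comfortably exceed
the jitter budget (see problem sizes below).

**MSAC.** Translation hypotheses are the individual correspondence
displacements; hypotheses are scored by the quadratic loss truncated at
`inlier_tol² = 4 px²`. With at most `max_iters = 500` correspondences every
hypothesis is scored (exhaustive and deterministic — the common case);
beyond that, random sampling with confidence-based early termination is
used, seeded from the pipeline seed. The final estimate is the mean
displacement of the winning hypothesis's inliers; `min_matches = 3` and
`min_inliers = 3` guard against single-match consensus for a 2-dof model.
Failure is a normal "not found" return that triggers the full-overlap
fallback; a strip estimate outside the stage-motion range also retries on
the full overlap before the link is declared invalid.

## Repair and global alignment

Invalid north links are replaced by the component-wise mean of the valid
north links in their grid row — one row shares one vertical stepping error —
falling back to the global north mean when the row has none; west links
symmetrically by grid column. Means are computed once over originally valid
links only (no chaining), so repair is idempotent, and repaired links keep a
sentinel match count.

Edge weights are (1/n) / max(1/n) over finite-count edges, so weights lie in
(0, 1] and the weakest finite edge has weight exactly 1; sentinel-count
edges get 1 + `penalty_constant` (default 1), strictly heavier than every
finite edge, so they enter the spanning structure only where no finite route
exists (e.g. across background regions). Positions accumulate tree-edge
translations from the root and are shifted so min x = min y = 0.

For the shortest-path tree, Dijkstra runs from every vertex and the origin
minimizes the summed path weights; because the weights are ratios whose
sums can tie, the argmin is float-tolerant (anything within 1e-9 relative of
the minimum counts as tied) and ties resolve to the smallest (row, col).
Predecessor ties in the SPT resolve the same way. Prim's MST is computed
with deterministic (sorted) node and edge insertion.

## Composition and metrics

Tiles are pasted at positions rounded to the nearest pixel, in row-major
scan order, later tiles overwriting earlier ones; no interpolation or
blending, so the clean-grid result stays bit-exact and misalignments remain
visible as seams. A configurable frame-size cap guards against runaway
positions.

Overlap RMSE is computed per grid-adjacent pair on the intersection of the
placed rectangles, with intensities divided by the dtype maximum (so 8-bit
values are comparable across datasets); pairs with empty intersection are
excluded and counted, and an all-excluded grid yields NaN with a warning.
D_err compares tile centroids after both position sets are normalized to the
same origin. MSE/PSNR crop to the common top-left-aligned region when the
frames differ by a border row/column (with a warning), and PSNR is +inf
exactly when MSE is 0.

## Synthetic data

The generator emulates grid acquisition by cropping tiles from one source
image, so ground truth is exact by construction. Two sources: a
histology-like texture (smoothed noise background, 215→175 gray, plus
~1 dark blob per 90 px² with radius 1.3–3 px and contrast 120–200 on the
8-bit scale — dense enough that a 5% strip of any tile carries tens of
strong blobs) and a binary resolution-chart pattern (bar triplets at four
scales in the central 60%, empty margins so corner tiles of a 10 × 10 grid
are featureless and force the repair path). Stage jitter is integer-valued
so that ground truth stays exact under pixel rounding; shading is the same
multiplicative field on every tile (fixed-pattern vignetting, the hard case
for intensity-based stitchers: per-tile gain does not cancel between
neighbors); noise is additive Gaussian, applied after shading; background
tiles are constant at the modal intensity.

What the generator does **not** emulate: optical blur differences between
tiles, rotation/scale error, nonlinear lens distortion, sensor fixed-pattern
noise, or the repetitive micro-architecture of real tissue. Passing tests
therefore demonstrate correctness of the pipeline's geometry and robustness
mechanisms, not field performance on arbitrary real slides.

## Default problem sizes

The shipped tests and the acceptance script use grids sized for a laptop-class
single-CPU run while preserving the protocol's structure: the clean and
chart grids are 10 × 10 with 30% overlap at 160 px tiles (an 8 px strip);
the jitter study uses a 5 × 5 grid at 500 px tiles, ±5 px jitter, and noise
σ = 1% of the 8-bit range. The 500 px tile is deliberate: the stage-model
window is ±2% of the tile (±10 px), exactly the worst-case relative jitter
of two independently ±5 px-jittered tiles, and the 25 px strip keeps ≥15 px
of shared content under worst-case jitter. Scaling tile size up changes
none of the logic, only runtimes.

## Known limitations

- Translation-only: any real rotation between tiles spreads residuals the
  model cannot absorb.
- The nominal overlap must be approximately right; a badly wrong value
  defeats both the restricted strips and the validity filter.
- Very thin strips (≲8 px) carry few blobs; for small tiles the
  full-overlap fallback triggers more often, which costs time but not
  accuracy.
- Repair assumes stage errors are consistent within a row/column; a
  one-off mechanical glitch inside an all-background row is unrecoverable
  by averaging.
- No blending: seams at true intensity discontinuities (e.g. shading
  mismatch between neighbors) remain visible by design.
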