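# gridstitch

Fast feature-based stitching of grid-acquired microscope tiles into a
whole-slide mosaic.

Whole-slide imaging scans a specimen as an M × N grid of overlapping
high-magnification tiles. Stitching them back together is harder than it
looks: tissue texture is repetitive, background tiles are featureless, and
with hundreds of tiles both runtime and error propagation matter.
`gridstitch` addresses all three with a pairwise-then-global design aimed at
users who need a reproducible, inspectable stitcher for bright-field,
phase-contrast, or fluorescence tile grids.

## Method

1. **Pairwise registration.** For every tile and its north/west neighbor
   (2MN − (M+N) pairs), scale-space determinant-of-Hessian blobs are
   detected in a thin strip — 5% of the tile width/height — of the shared
   overlap, described by shading-invariant normalized patches, matched
   (mutual nearest neighbor + ratio test), and fed to MSAC to estimate a
   pure translation (t_x, t_y). Scale and rotation are fixed by the
   acquisition geometry and are not estimated. If the strip fails (too few
   matches or inliers, or an implausible estimate), the full nominal
   overlap is retried; links that still fail are marked invalid.
2. **Stage-model filter.** Translations outside the mechanically plausible
   range — the nominal overlap offset ± 2% of the tile dimension — are
   discarded.
3. **Repair.** Invalid north links take the component-wise mean of the
   valid north links in their grid row (global mean if the row is empty);
   west links symmetrically by column.
4. **Global alignment.** A weighted graph connects each tile to its
   neighbors; the edge weight is the normalized inverse of the matched
   feature count, so well-supported links are cheap. Repaired links carry a
   penalty weight. Tile positions come from the MN − 1 edges of either the
   Prim minimum spanning tree or the Dijkstra shortest-path tree rooted at
   the vertex with minimal total path weight.
5. **Composition + metrics.** Tiles are pasted at rounded positions with no
   blending (misalignments stay visible). Reported metrics: mean overlap
   RMSE on unit-normalized intensities, and — when ground truth exists —
   centroid distance error D_err, MSE, and PSNR.

## Worked example

Generate a ground-truthed synthetic 4 × 4 grid (25% overlap, ±2 px stage
jitter, mild noise) and stitch it:

```sh
gridstitch synth --rows 4 --cols 4 --overlap 0.25 --tile-size 200 \
    --jitter 2 --noise 2.0 --seed 11 --out demo/tiles
gridstitch stitch --input demo/tiles --rows 4 --cols 4 --overlap 0.25 \
    --graph mst --out demo/out
```

which prints (abridged):

```json
{
  "n_links": 24,
  "n_strip": 14,
  "n_full_overlap": 9,
  "n_invalid": 1,
  "n_repaired": 1,
  "n_tree_edges": 15,
  "pairwise_time_fraction": 0.99,
  "overlap_rmse": 0.011013969237313884
}
```

All 24 pairwise links were computed (14 from the 5% strip alone, 9 from the
full-overlap fallback); one implausible estimate was discarded and repaired
from its column average; 15 = MN − 1 tree edges place the 16 tiles. The
overlap RMSE of 0.011 (intensities in [0, 1]) reflects the sub-pixel
residuals of a jittered, noisy grid. Comparing against the generator's
ground truth:

```sh
gridstitch eval --tiles demo/tiles --rows 4 --cols 4 --overlap 0.25 \
    --positions demo/out/positions.csv --stitched demo/out/mosaic.tif \
    --truth-positions demo/tiles/truth_positions.csv \
    --truth-image demo/tiles/source.tif
```

reports `"d_err": 0.104` — the mean tile-centroid error is about a tenth of
a pixel. With `--jitter 0 --noise 0` the same workflow is exactly
error-free: `d_err = 0`, `mse = 0`, `psnr = inf`, and `mosaic.tif` is
bit-identical to `source.tif`.

The same functionality is available as a library
(`gridstitch.stitch_grid`, `gridstitch.generate_grid`, ...); see the module
docstrings and `docs/methods.md`.

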