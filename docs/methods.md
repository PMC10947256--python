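# Methods

## Measurement model

Vein density is estimated as skeleton length per leaf area. After
segmentation and thinning, every vein is a one-pixel-wide 8-connected
curve, and its pixel count is used as its length in pixel units: an axial
step contributes exactly one pixel side, a diagonal step also counts one.
The estimator therefore carries a known, geometry-dependent bias: it is
essentially exact for near-axis-aligned strands and undercounts slanted
strands by up to √2 − 1 per diagonal step (about −5% on the reticulate
test geometry below). A √2-weighted alternative
(`diagonal_corrected_length`) is provided as a diagnostic but is not the
reported quantity, keeping the measurement definition simple and
comparable across images. With pixel side `p` (µm) and an `h × w` px
raster,

    length [µm]   = n_skeleton_pixels · p
    area [mm²]    = h · w · p² · 10⁻⁶
    density       = length / area        [µm mm⁻²]

The area always describes the raster actually measured; a mismatch with
the configured dimensions flags the row rather than aborting the batch.

## Segmentation chain and its parameters

| parameter | default | meaning |
|---|---|---|
| `blur_w` | 20 | mean-filter half-width; kernel (2w+1)² px |
| `clahe_clip_limit` | 0.01 | CLAHE clip limit (fraction of tile count) |
| `clahe_tile_grid` | 8×8 | CLAHE tiles (rows, cols) |
| `threshold_override` | none | fixed threshold in [0,1] instead of Otsu |
| `invert_foreground` | true | complement so dark-stained veins become 1 |
| `trim_factor` | (required) | spurs shorter than this many px are pruned |
| `auto_trim_trigger_fraction` | 0.15 | spur-pixel fraction that arms auto trim |
| `monocot_branch_length_to_keep` | 0 | commissural span threshold, px; 0 = off |

The blur kernel is fixed as (2w+1)×(2w+1): the half-width formulation is
taken as primary where a nominal kernel size would disagree with it.
Borders use replicate padding so margins are not darkened, which would
otherwise bias the Otsu threshold. The blur half-width should be of the
order of the vein stroke width: the default w = 20 suits wide
bundle-sheath strands imaged at ×100; the synthetic validation strokes
are 5 px wide, so those runs use w = 3. Otsu's threshold is computed on a
fixed 256-bin histogram over [0, 1] (not over the image's min–max range),
so a given intensity always falls in the same bin regardless of image
content; a constant image yields an empty, flagged mask.

## Skeleton graph

Branch points are skeleton pixels with ≥ 3 foreground 8-neighbours, end
points those with exactly 1. Thinning routinely produces touching branch
pixels at junctions; these are grouped into junction clusters, and edges
are maximal pixel paths traced between clusters/tips. An edge's geodesic
length is its pixel count including both terminals. Connected components
with no nodes are stored as single closed cycle edges; isolated pixels
are retained separately.

### Spur trimming

A spur (one terminal a tip, the other a junction) is deleted when its
length is strictly below the trim factor; floating fragments
(tip-to-tip segments, isolated pixels) below the same scale are equally
superfluous and fall to the same rule. Deletion is shortest-first: each
round removes all deletable pieces of the current minimum length,
re-detects branch points, and repeats until no piece below the trim
factor remains. Because pruning a spur can demote its junction and merge
the surviving branches, naive batch pruning is not monotone in the trim
factor — a harsher factor can orphan pixels into configurations a gentler
factor would still delete. The shortest-first order removes that
order-dependence: the cascade for a larger factor is a continuation of
the cascade for a smaller one, so trimming is provably monotone
(pixel sets only shrink as the factor grows) and idempotent.

When an edge is deleted, its junction-side terminal pixel is itself
removed only while it is a *simple point* (its remaining neighbours form
one 8-connected component), which clears the one-pixel nubs that diagonal
adjacency leaves at junctions without ever severing a surviving vein.

### Automatic trim factor

When thinning artefacts dominate — operationalized as spur pixels
exceeding `auto_trim_trigger_fraction` of the skeleton — the trim factor
becomes mode(spur lengths) + 1, ties broken toward the smaller length, so
spurs of the modal length fall to the strict-< rule. Veins truncated by
the image frame also end in tips but are real anatomy: spurs whose tip
lies within a border margin (the pipeline uses 2·blur_w + 1 px, the scale
over which a cut vein's skeleton recedes from the frame) are excluded
from the spur statistics. Without this exclusion the modal length on
frame-crossing networks lands on legitimate vein segments and the auto
rule deletes real veins.

### Commissural removal (monocot mode)

Commissural veins — the short transverse connections between longitudinal
veins in grass leaves — are identified as edges whose two terminals are
branch points in distinct junction clusters and whose terminal-to-terminal
*Euclidean* distance is strictly below `monocot_branch_length_to_keep`.
Setting the threshold to 0 disables removal. The rule is identifiable
only when commissural spans are shorter than the along-vein distance
between junctions, which holds in grass anatomy; the threshold should sit
between the interveinal distance and that junction spacing. Spur edges
are never touched by this operation, and junction pixels on the
longitudinal veins are preserved (with the same simple-point nub
cleanup), so the rails' pixel sets are unchanged.

## Synthetic study conditions

The generator emulates the imaging conditions of starch-stained leaf
micrographs: 1392 × 1040 px frames at 0.65 µm/px (a 3.3 Mpx microscope
camera at ×100), strands 5 px wide, background 0.85 with Gaussian noise
(σ = 0.03) and a 10% linear illumination ramp, vein level 0.25. Parallel
networks use 8 longitudinal veins spaced 150 px (≈ 98 µm, within the
grass interveinal range) with commissural rungs every 220 px, aligned
across gaps so the along-rail junction spacing stays above the rung span
(as in grass leaves, where commissural veins are short relative to their
spacing along a vein). Reticulate networks use wavy primaries joined by
slanted, staggered secondaries forming closed areoles. Geometry is a
deterministic function of the geometric parameters; the seed drives only
the noise field. Ground truth is the analytic arc length of the
centreline polylines — not a pixel count — so recovery tests bound the
pixel-count estimator's bias as well as segmentation errors.

What the generator does **not** emulate: staining inhomogeneity along a
vein, out-of-focus blur, vein-width variation and tapering, bundle-sheath
cell texture, and curved/occluded tissue. Passing recovery tests
therefore demonstrate the correctness of the measurement chain under
controlled contrast, not robustness to every failure mode of real
staining; the deferred manual check (overlays + rejection list) remains
the guard for those.

Typical recovery under these conditions (recomputed by
`scripts/acceptance.py`): parallel networks within ~1% of ground truth,
reticulate networks ~7% low — almost entirely the diagonal undercount of
the pixel-count length on slanted secondaries — and rails-only recovery
within ~0.5% in monocot mode.

## Numerical and design choices

- 8-connectivity and 0-based (row, col) coordinates throughout.
- Otsu ties (equal between-class variance) resolve to the smallest bin.
- Trimming uses strict inequality: `trim_factor = 0` is the identity, and
  a spur exactly at the factor survives.
- The auto-trim mode ties break toward the smaller length.
- Edge tracing treats touching branch pixels as one junction; the
  reported branch-point list still contains every ≥3-neighbour pixel.
- Batch processing is single-threaded and free of random state; rows are
  written in sorted filename order, so re-runs are byte-identical.
- The interactive per-image check is replaced by a file-based review:
  overlays on disk plus a rejection list, applied after the batch
  (`apply_review`), which marks rows excluded without deleting them.
- 16-bit integer rasters are min–max rescaled to [0, 1] (microscope
  captures rarely fill their nominal range); 8-bit rasters are scaled by
  255.

## Known limitations

- The pixel-count length estimator undercounts strongly slanted veins
  (up to ~8% in the worst orientation); use the diagonal-corrected
  diagnostic if orientation-independent lengths matter.
- Broken strands are not re-joined (no gap bridging), and vein order,
  width and areole statistics are out of scope.
- The commissural rule fails when transverse veins are longer than the
  along-vein junction spacing; in that regime set
  `monocot_branch_length_to_keep = 0` and report total density.
- CLAHE amplifies background noise in vein-free regions; with very sparse
  networks a threshold override can outperform Otsu.
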