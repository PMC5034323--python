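# Methods

## Scope and model

`isletquant` quantifies endocrine cell mass on single pancreas sections by
exhaustive measurement rather than sampling. The quantity of interest is

    percent endocrine area = 100 · (hormone-positive area) / (pancreas area)

where the pancreas area is a manually drawn contour minus qualifying
exclusion regions, and the hormone-positive area is the pixel-wise union of
the thresholded hormone channels. Everything downstream — islet records,
cell typing, size distributions, sampling simulations — is derived from the
same rasters, so section-level totals are conserved exactly (sums of
per-islet areas reproduce the composite mask pixel count; per-type nucleus
counts sum to the number of classified nuclei).

## Coordinate and rasterization conventions

Pixel-index space, origin top-left, `x` = column, `y` = row, 0-based. Pixel
`(row, col)` covers `[col, col+1) × [row, row+1)`; its center is
`(col+0.5, row+0.5)`. A pixel belongs to a polygon iff its center is inside
(even-odd rule, boundary exclusive). Physical µm coordinates are pixel
coordinates × `pixel_size`. With this convention a square contour
`(0,0)–(100,100)` rasterizes to exactly 10 000 pixels.

## Pipeline stages

### Background subtraction

Rolling-ball background: grayscale opening with a ball structuring element
of radius `rolling_ball_radius_px` (default 50 px), subtracted from the
channel and clipped at 0, applied to the whole raster with no regional
selection. Out-of-frame values are treated as +∞ during erosion and −∞
during dilation, i.e. the ball rolls only under measured data. For radii
above 16 px the background is estimated on a block-minimum downscaled
raster (factor `radius // 8`) and upsampled bilinearly; large balls are
insensitive to detail finer than the block, and the background is clipped
to never exceed the image. The ball radius must exceed the half-width of
the largest genuine structure, otherwise broad islets are flattened — the
default suits islets up to ~100 µm across at 1 µm/px; raise it for larger
structures.

### Tissue mask

The pancreas outline polygons are rasterized and united; each exclusion
polygon (vessel, duct, fat, inter-lobe space) is subtracted only if its own
rasterized area is strictly greater than `exclusion_min_fraction` (default
0.0005, i.e. 0.05 %) of the outline area. Smaller exclusions are left in
the tissue: they are below the scale at which normalization is affected,
and dropping them keeps manual contouring workload bounded. Areas are
reported in µm².

### Thresholding and binarization

Thresholds are per-channel intensities, set manually (the primary mode; a
run's values are written to a plain-text `key=value` file) or derived by
Otsu's between-class-variance criterion (`auto_threshold`). Comparison is
inclusive (`channel ≥ threshold`), and binarization is AND-ed with the
tissue mask, so pixels outside the pancreas contour are always 0. Note that
Otsu assumes a genuinely bimodal histogram: on a channel whose foreground
is a tiny pixel fraction (e.g. a sparse somatostatin channel) it can split
the background instead — use manual thresholds for such channels.

### Islet segmentation

Stained pixels are grouped into islet structures by morphological closing
with a disk of `close_radius_um` (default 5 µm), hole filling, and
8-connected component labeling. Closing bridges gaps between neighboring
cells; hole filling annexes unstained intraislet space (capillaries,
stroma), so `total_islet_area ≥ endocrine_area` by construction. Components
with filled area below `min_islet_area_um2` (default 0: single cells count)
are dropped. Labels are assigned 1..N in raster-scan order of each
component's first pixel — deterministic, no tie possible. On noisy images a
`min_islet_area_um2` of ~50 µm² (well under the 178 µm² single-cell area)
rejects suprathreshold noise specks while keeping every singlet.

### Shape metrics

* **centroid** — mean of member pixel centers × pixel size.
* **perimeter** — length of the component's marching-squares boundary
  polygon after Douglas–Peucker simplification with tolerance 1 px. The raw
  marching-squares contour overestimates oblique smooth boundaries by up to
  ~8 %; sub-pixel simplification removes the rasterization staircase but
  preserves true corners. Measured calibration: disks of radius 10/30/100 px
  give circularity 0.95/0.99/0.995 (monotone toward 1), a rasterized square
  gives 0.789 vs π/4 = 0.785. The common pixel-step-weight and Crofton
  perimeter estimators were rejected: both are accurate for disks but
  mis-measure squares by ~11 %.
* **circularity** — `4π · total_islet_area / perimeter²`, clipped at 1.0
  (rasterization can push it slightly above).
* **Feret diameter** — maximum pairwise distance between boundary pixel
  centers plus one pixel (pixel extent), computed by convex hull + rotating
  calipers with an exact brute-force fallback for degenerate (≤3 points or
  collinear) inputs; the calipers result equals the O(n²) maximum exactly.

### Nucleus segmentation and cell typing

The binary nuclei mask is partitioned by a distance-transform watershed:
seeds are local maxima of the Euclidean distance transform with a minimum
separation of 0.7 × `expected_nucleus_diameter_um` (default 7 µm);
watershed on the negated transform assigns every foreground pixel to
exactly one nucleus (components that produce no seed keep one label of
their own, so the partition is total).

Each nucleus is typed by its perinuclear ring: the nucleus region dilated
by `ring_width_px` (default 1) in the Chebyshev (8-connected) metric, minus
the bodies of *all* nuclei — a ring pixel claimed by a neighboring nucleus
is never sampled. The hormone with the strictly largest positive-pixel
count in the ring wins; all-zero votes (exocrine/endothelial/stromal
nuclei) give "unclassified", retained in the table. Exact ties are resolved
by a configured hormone priority order (default: channel order) and
flagged, so ties are auditable rather than silently arbitrary. A nucleus is
assigned to the islet whose label lies under its centroid pixel; nuclei
outside every islet get no islet id.

## Stereology estimators and simulations

* **Point counting** — a regular square grid (default 25 µm spacing,
  configurable offset); a vertex is positive iff the pixel containing it is
  positive; the estimate is `100 · n_positive / n_total`. The percent is
  carried at the results-table display precision of 3 decimals and reported
  half-up at 2 decimals (so 30 of 945 vertices → 3.175 → 3.18 %); the
  unrounded value is kept alongside for statistical use, and the estimator
  is unbiased when averaged over uniform random grid offsets.
* **Panel selection** — the section frame is tiled into non-overlapping
  panels (default 868 × 662 µm, a typical 10× field; edge panels may be
  smaller). Panels are ranked by descending content-mask pixel count (ties
  by index), and the cumulative estimate after the top-k panels is
  `100 · endocrine / tissue` within those panels — at k = all panels this
  reproduces the whole-section estimate bit-exactly, which is the package's
  internal consistency anchor. Normalization uses tissue-within-panel, not
  whole-panel area, consistent with the pipeline's normalization rule; a
  caller can pass a full-frame tissue mask to get the whole-panel variant.
* **Every-nth-section** — percent endocrine area of sections 0, n, 2n, …
  (default n = 50) through a block, with the observed range.
* **Block schemes** — estimates of whole-organ percent endocrine area from
  block subsets: `all` (truth), `single:<i>`, `region:<head|body|tail>`,
  `one-per-region` (one random block per region), `random:<k>`. Estimates
  are pancreas-area-weighted means; random schemes run 5 seeded replicates.
  The five schemes are this package's concrete reading of "selection
  designs in common use" and are exposed individually so users can redefine
  them.
* **Largest-N ratios** — cell-type count ratios over the N largest islets
  (by filled area, default N = 100) against the all-islet ratios; zero
  denominators are flagged, not raised.

## Analytics

Sizes are expressed as cell-equivalents — islet area / 178 µm², a nominal
single endocrine cell area — and binned with
`bin index = floor(log10(CE) / bin_width)`, default width 0.25 log10 units.
Composition fractions are averaged per islet (each islet one sample,
mean ± SEM); a pooled-count mode would weight big islets more and is easy
to compute from the records if wanted. The histogram conserves counts and
area fractions exactly. Shape scatter features (log10 CE, circularity,
Feret) are z-scored per axis, and the density score is the inverse mean
distance to the k nearest neighbors (default k = 10; N−1 neighbors when
N ≤ k; a single islet gets density 0, flagged). kNN inverse distance was
chosen over kernel density because it is bandwidth-free and directly
checkable against a brute-force oracle. Degenerate zero distances are
regularized with ε = 1e-12, so identical islets share one finite density.

## Synthetic sections

The generator emulates: scattered islets with log-normal cell counts
(median 5 cells, ln-sd 1.1, capped at 400 — singlets are the most common
structure, as in real tissue), uniform or clustered islet placement
(clusters of Gaussian dispersion 150 µm), a size-dependent composition in
which the alpha fraction rises with log islet size (slope 0.06 per decade,
taken from the beta fraction; baseline insulin/glucagon/somatostatin =
0.78/0.12/0.10), cells as 178 µm² cytoplasm disks packed by a phyllotaxis
(sunflower) layout with 10 % nearest-neighbor overlap, concentric 3 µm
nuclei, a constant background (10) with a smooth gradient (amplitude 5) and
Gaussian noise (sd 10 = 5 % of the 200 signal level), and optional
rectangular signal-free exclusions placed clear of islets. Placement uses
rejection sampling with a 15 µm clear rim between islets (wider than twice
the default closing radius, so planted and segmented islet counts can be
compared one-to-one); on an overcrowded frame, fewer islets are placed and
the ground truth records what was placed.

It does **not** emulate: polygonal/irregular cell shapes, exocrine texture
or autofluorescence, anisotropic illumination beyond a linear gradient,
out-of-focus blur, chromatic misregistration, or 3-D section thickness.
Passing tests therefore demonstrate the correctness of the measurement
machinery under controlled conditions, not robustness to every real-world
artifact; thresholds on real material remain an operator responsibility.

All randomness flows from a single `numpy` generator seeded by `seed`;
outputs are bit-identical across runs for the same parameters.

## Problem sizes and determinism

The test suite and the acceptance script run on synthetic sections between
600² and 2000² px (1–4 µm/px), 8–400 islets — sizes chosen so the full
suite completes in a few minutes on one CPU while still exercising
full-size rasters. Every stochastic check is seeded; hypothesis property
tests are derandomized.

## Known limitations

* Otsu auto-thresholding misbehaves on channels with near-zero foreground
  (see above); the pipeline's primary mode is manual thresholds.
* The rolling-ball radius trades background fidelity against flattening of
  structures wider than the ball; no flat-field correction is attempted.
* Circularity of structures a few pixels across is biased low (boundary
  polygon resolution); values are reliable from ~10 px radius upward.
* The perinuclear ring samples a 1-px shell; at pixel sizes much coarser
  than 1 µm/px the ring leaves the cytoplasm and typing degrades — set
  `ring_width_px` relative to the calibration.
* Sections are treated independently; no 3-D reconstruction or islet
  tracking across serial sections.
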