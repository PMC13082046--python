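# Methods

## Coordinate model

All spatial data live in global micrometre coordinates, y increasing
downward, with the frame origin at the top-left corner.  A pixel `(r, c)`
of a frame with pixel size `s` covers the half-open box
`[origin_x + c·s, origin_x + (c+1)·s) × [origin_y + r·s, origin_y + (r+1)·s)`.
Half-open boxes make transcript binning a true partition: tiling a frame
tiles its molecules with no loss or duplication.  The default pixel size
is 0.2125 µm/px (the Xenium morphology-image convention); the simulator
uses coarser grids (0.25–0.5 µm/px) purely for speed.  Whether global or
tile-local coordinates are used is immaterial: the configurable frame
origin covers both.

## Transcript-density pseudoimage

The density channel sums an isotropic Gaussian kernel of spread σ at
every retained molecule location, evaluated at pixel centers.  Choices:

- **σ is interpreted in pixels** (default 2.5), because a kernel placed
  on a discrete pixel grid reads most naturally in pixel units; σ in µm
  is supported via `sigma_units="um"` and converted through the frame's
  pixel size.
- **Kernel truncation** at 4σ by default bounds the cost at O(N) with a
  per-molecule error below e⁻⁸; the truncation radius is configurable
  and an exact O(N·pixels) summation serves as the oracle in the test
  suite (agreement < 1e-6 at 6σ truncation).
- **Scaling**: min–max to [0, 1] per image (i.e. per tile when tiles are
  processed independently, matching how tiles are fed to a model).  A
  constant image maps to zeros, not 0.5, so empty tiles stay empty.
- **DAPI normalization** caps at the image-wide 99th percentile then
  divides by it; computed per input image.  All-zero images map to
  zeros.
- The density is gene-agnostic by design: distinguishing genes would tie
  the representation to a fixed panel and break transferability across
  experiments.

## Quality control and tiling

Molecules with decoding quality `qv < 20` are discarded (threshold
inclusive: `qv = 20` is retained).  Tiles are sampled uniformly without
replacement from a stride grid (stride = tile_size/2 by default, to
bound the candidate set); a tile qualifies with ≥ 200 pixels inside
cellular regions and ≥ 15 distinct cells intersecting it.  A cell counts
as soon as one of its pixels lies in the window — the weaker reading,
chosen because requiring full containment would bias against large
cells.  Tile size itself is a free parameter (default 256 px, a standard
segmentation input scale).  Qualifying tiles are split uniformly at
random into train/test sets (reference protocol: 1000 tiles, 800/200).
The training exporter records the reference fine-tuning configuration
(300 epochs, learning rate 0.001, weight decay 1e-5) alongside each
image/mask pair; actually training a GPU segmentation model is out of
scope for this package — the exporter plus the backend adapter define
the contract.

## Nuclear expansion baseline

Each nucleus grows uniformly by a distance (default 5 µm) unless it
meets a neighbor first.  The collision rule is formalized as a
nearest-nucleus constraint: a background pixel joins the nucleus whose
pixel set is closest (Euclidean distance between pixel centers,
converted to µm), provided that distance ≤ the expansion radius.
Equidistant pixels go to the smaller label — a probability-zero event on
real data but necessary for reproducible tests.  Distances are measured
pixel-center to pixel-center rather than with sub-pixel refinements so
the operation is exactly checkable against an exhaustive per-pixel
search (and is, on every test run).  The implementation sweeps one
distance transform per label in ascending label order; strict
improvement updates make the tie rule exact because equal integer
offsets yield bit-identical distances.

## Evaluation metrics

- **Image IoU**: `IoU(i,j) = |G_i ∩ P_j| / |G_i ∪ P_j|` over pixel sets,
  background excluded.  Each predicted cell takes its column maximum;
  the tile score is the unweighted mean over *all* predicted cells
  (cells with no ground-truth overlap contribute 0).  Dataset summaries
  average tile means, not pooled cells.  A tile with no predictions has
  an undefined mean, is flagged NaN, and is excluded from averaging.
- **Gene IoU**: the same construction on per-cell transcript-index sets,
  with molecules assigned by spatial containment (half-open pixel rule)
  after QC filtering.  Predicted cells with zero assigned molecules are
  excluded from the tile mean, since 0/0 is undefined — unlike the
  image metric, where every predicted cell has pixels.
- **Alignment**: (g, p) is kept iff IoU ≥ 0.3 and the two cells are
  mutual best matches; argmax ties break toward the smaller label and
  are reported.  The result is one-to-one by construction and asserted.

## Morphology

Features are computed from the cell's boundary polygon in µm.  Masks
are bridged to polygons by tracing the outer boundary along pixel
corners (implemented as the exterior of the union of pixel squares), so
polygon area equals pixel count × pixel_size² exactly and the perimeter
is the staircase length; interior holes are ignored.  A smoothed
contour would give shorter perimeters and slightly different
circularities — the corner convention is used consistently for all
methods being compared, which is what the comparisons require.

- Eccentricity is `1 − λ₂/λ₁` from a PCA of the raw polygon vertices;
  vertex density therefore influences it (documented caveat).  Collinear
  vertex sets return the boundary value 1 with a warning.
- Roundness divides the area by the area of the **exact** minimum
  enclosing circle (Welzl's move-to-front algorithm, deterministic
  shuffle); an approximate circle would bias roundness upward.
- Aspect ratio uses the minimum-area rotated bounding rectangle
  (rotating-calipers result via the computational-geometry library) and
  is normalized to long/short ≥ 1 so that larger always means more
  elongated.  Note the minimum-area rectangle is not always unique:
  distinct orientations can tie in area with different side ratios, so
  oracle comparisons accept any near-minimal candidate.

## Downstream analyses

Count matrices tally QC-passing molecules per (aligned cell, gene); the
gene axis is fixed across segmentations so matrices are comparable.
Clustering: library-size normalization to the median, log1p, PCA
(≤ 50 components), kNN graph (k = 15), Leiden.  The resolution is tuned
by bisection over [0.01, 3.0] (≤ 40 evaluations) to reach k = 10
clusters, accepting {9, 11} then {8, 12} as fallbacks; all evaluated
(resolution, k) pairs are cached so non-monotone blips still count.
PCA dimensionality, kNN k and the normalization target are ecosystem
defaults, configurable.  Agreement uses scikit-learn's ARI, AMI,
homogeneity and completeness.

Morphology embedding: z-scored features (constant features dropped with
a warning), UMAP with n_neighbors = 30, min_dist = 0.01, Euclidean
distance, plus per dataset-and-type centroids.  Classification:
unknown/unassigned cells excluded, the five most abundant types kept,
stratified 80/20 split, random forest with 500 trees and class weights
inversely proportional to training-set class frequency.  Accuracy,
per-class one-vs-rest precision/recall/F1, macro-F1 and macro ROC-AUC
are implemented from first principles (ROC-AUC as the tie-averaged
Mann–Whitney statistic, equivalent to the trapezoidal ROC area); the
learner is scikit-learn's forest, but every reported metric is a pure
function of its predictions, cross-checked against scikit-learn's
metric functions in the tests.

## Synthetic tissue generator

The generator emulates the data regime in which fixed-radius expansion
fails: contiguous, space-filling, non-circular cells.

Geometry: blue-noise (Poisson-disc) seed points; each cell gets a
type-dependent radius scale, elongation and orientation; pixels are
partitioned by seeded watershed on the minimum of per-cell anisotropic
distance fields (two jittered subsites per cell perturb the tessellation
away from clean ellipses).  Nuclei are ellipses with a fixed area
fraction of their cell (default 0.35), mildly co-elongated, displaced
from the cell centroid by `offset_fraction × √(A/π)` in a random
direction, and clipped to the cell — so nuclei are strict subsets of
cells by construction.

Expression and noise: each cell type draws a multinomial gene profile
from a symmetric Dirichlet (concentration 0.3 → distinct, sparse
profiles); per-cell molecule counts are Poisson (default mean 100);
positions are uniform over the cell's pixels (so cell-born molecules are
inside their cell by construction); qv = 20 + Gamma(2, 5).  Background
molecules arrive as a spatial Poisson process (default 0.05/µm², ≈ 9 %
of all molecules) with 85 % of their qv mass below 20, so the Q ≥ 20
filter removes mostly background — the filter's purpose.  DAPI is the
nucleus indicator times a per-nucleus brightness, Gaussian-blurred
(σ = 1 px), plus clipped Gaussian read noise.

Defaults (80 cells, 6 µm mean radius, elongation 1–3, offset fraction
0.3, 5 types, 50 genes) were fixed once as a realistic desk-scale
Xenium-like tissue.  What the simulator does **not** model: optics (PSF,
out-of-focus light), 3-D nuclei and z-stacks, gene-specific subcellular
localization, segmentation-adversarial structures such as overlapping
cells.  Passing tests therefore demonstrate correctness of the
*computational* pipeline and the direction of the expansion baseline's
biases, not real-tissue accuracy of any particular segmenter.

## Numerical conventions

- Constant images scale to zeros; empty transcript sets give zero
  density maps, not errors.
- All randomness flows from explicit integer seeds (NumPy `default_rng`,
  scikit-learn/scanpy/UMAP `random_state`); identical configs reproduce
  reports bit-identically.
- Degenerate polygons (zero area, coincident vertices) raise; collinear
  eccentricity and empty-seed segmentation return flagged boundary
  values instead, since they occur on valid inputs.
- Tie-breaks (expansion collisions, alignment argmax) always resolve
  toward the smaller label.

## Problem sizes

The shipped tests and demo configurations run on 256–512 px frames with
30–80 cells, ~100 molecules per cell and 1000-cell planted count
matrices — sizes chosen so the whole suite exercises every stage,
end-to-end, on a single CPU in a few minutes.  All of them scale up by
configuration only.

## Known limitations

- The classical fallback segmenter exists to exercise the evaluation
  stack without GPU weights; it is deliberately simple and is not a
  substitute for a trained model's accuracy.
- The nearest-nucleus collision rule is a documented formalization of
  "expand unless you hit a neighbor"; production pipelines may resolve
  collisions slightly differently near three-way junctions.
- Gene IoU excludes transcript-free predicted cells, so a segmentation
  that fragments background into empty cells is penalized by image IoU
  but not by gene IoU — read the two metrics together.
- Eccentricity from raw polygon vertices is resolution-dependent on
  pixel-traced contours; compare it only between masks rasterized on the
  same grid.
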