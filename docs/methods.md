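# Methods

## Problem and model

A padlock-probe / rolling-circle-amplification (RCA) experiment on a tissue
section yields, per homolog channel, a set of bright sub-micrometer spots,
each representing one detected transcript molecule, plus a nuclear stain.
The analysis has three layers:

1. **per-cell counting** — segment nuclei, define each cell as its nucleus
   plus a fixed-distance neighborhood, count spots per cell and homolog;
2. **categorical classification** — partition cells by their (X, Y) counts
   and normalize signal counts per 1000 cells so differently sized sections
   are comparable;
3. **spatial statistics** — ask whether the X- and Y-labeled point patterns
   are segregated in space beyond what random labeling of the same positions
   would produce, and compare dorsal against ventral counts.

## Image quantification

* **Nuclei**: global two-class Otsu threshold on the raw nuclei channel
  (a log-intensity variant is available via a flag), 8-connected components,
  components below `min_area` (default 20 px², suppressing single-pixel
  noise) discarded, labels assigned 1..K in raster order of first pixel.
* **Cells**: every background pixel within Euclidean distance `d` (default
  20 px) of a nucleus takes the label of the nearest nucleus pixel set.
  Implemented as an ascending-label sweep of local distance transforms so the
  tie-break is explicit and deterministic: a pixel exactly equidistant from
  two nuclei goes to the lower label. Coordinates are 0-based (row, col)
  with pixel centers at integers.
* **Spots**: white top-hat with a disc structuring element (radius a free
  parameter — real acquisitions need per-sample tuning, so there is no
  universal default), manual threshold (> 0 required; a non-positive
  threshold would call every pixel), 8-connected components, one spot per
  component at its response-weighted centroid rounded to the nearest pixel.
  The centroid choice stabilizes downstream density maps; any interior point
  of the component would serve for counting.
* **Assignment**: a spot's cell is the cell-label value at its pixel;
  label 0 maps to the sentinel −1 (unassigned).

## Per-cell classification

The six categories (no signal; X=1; Y=1; mixed; X-specific x ≥ 2, y = 0;
Y-specific y ≥ 2, x = 0) are mutually exclusive and exhaustive, with *mixed*
defined as x ≥ 1 **and** y ≥ 1 — the only reading under which published
per-category rows sum exactly to their printed totals, which the acceptance
suite verifies on four such rows. The coarser three-class view (X-specific /
Y-specific / mixed among cells with ≥ 2 signals) is derived from the six-way
partition.

For four-gene co-expression categories (PX, PY, NX, NY), every compound
category such as "PX + NX ≥ 2" is read as *at least one signal of each named
gene*. The alternative reading (total ≥ 2 allowing one gene to be 0) cannot
be excluded arithmetically because the published categories overlap and obey
no sum constraint; the conjunctive reading is the one under which the
category names ("PX and Y", "NX and Y") are consistent across rows, and it is
what this package computes.

## Spatial statistics

* **Density maps**: each spot contributes one pixel to its gene's count
  image; the image is convolved with a truncated rotationally symmetric 2-D
  Gaussian (window 150 px — forced odd to 151 so the kernel is
  center-defined — SD 25 px). With unit-mass normalization (default) the map
  integrates to the spot count for interior spots; an unnormalized display
  variant is available. Coincident spots accumulate rather than saturate,
  which keeps the map linear in the spot set. No boundary correction is
  applied (plain convolution); mass within half a window of the frame edge
  leaks out.
* **Purity**: p = Y/(X+Y) ∈ [0, 1]. A bounded proportion makes the X- and
  Y-dominance cutoffs symmetric (x-dominant p ≤ 0.2, y-dominant p ≥ 0.8,
  boundaries inclusive on the dominant side); the raw ratio Y/X is a
  monotone transform with the same dominance sets. Pixels with total density
  below `eps` (default 10⁻³ × the mean positive total density) are masked as
  background — behavior at zero density is otherwise undefined.
* **Histogram**: 50 equal-width bins on [0, 1] by default (a free
  parameter); purity 1.0 falls in the last bin.
* **Permutation null**: each of `n_rand` (default 100) randomizations
  permutes the X/Y labels uniformly over the fixed spot positions, preserving
  both positions and label counts exactly, and recomputes densities, purity,
  histogram and category proportions. The total density X+Y is
  permutation-invariant, so the background mask is computed once and observed
  and randomized purities are compared on identical pixels (this also halves
  the work: only the Y density is recomputed per randomization). Bins with
  |observed − mean| > 3 SD (SD over randomizations, ddof = 1) are flagged
  with the sign of the deviation. The 95% CI for each category proportion is
  the percentile interval of the randomized proportions using conservative
  order statistics (`lower`/`higher` interpolation): with 100 randomizations
  a linearly interpolated interval is systematically too narrow and rejects
  an exchangeable observation ~7% of the time instead of ~5%; the
  conservative interval brings the exchangeable rejection rate to ~6%, and
  the calibration test in the acceptance suite checks the realized rate.
  Randomization *i* draws from an independent substream seeded by
  `(seed, i)`, so results are reproducible and order-independent.
* **Dorsal/ventral**: the border is the line through the midpoints of two
  landmark pairs, one pair spanning dorsal-to-ventral on each side of the
  section; pixels above the line are dorsal, on or below it ventral.
  Per-region X:Y count ratios with a zero denominator are flagged NaN and
  excluded from testing. The regional comparison uses a one-tailed Welch
  t-test (unequal variances, Welch–Satterthwaite df), implemented from the
  closed form; zero pooled variance is reported as degenerate rather than
  silently producing a statistic.

## Discriminating sites

A column of the pre-computed X/Y isoform alignment is discriminating when all
X isoforms carry one identical base in {A, C, G, T}, all Y isoforms likewise,
and the bases differ. N and gap columns never qualify: a ligation junction
needs an unambiguous base. Sites are reported in 0-based alignment
coordinates plus per-isoform ungapped coordinates for probe placement.
Alignment construction and probe ranking (arm thermodynamics, exon choice)
are out of scope. Percent identity is computed over columns where neither
sequence has a gap.

## Synthetic scenes

The generator emulates the statistical structure of a hybridized section:

* **Geometry**: an elliptical (or half-annular, or full-frame) tissue mask;
  nuclei placed by hard-core rejection sampling (grid-accelerated, bounded at
  1000 × n_cells attempts, explicit failure beyond that) with a minimum
  center separation; radii Normal(mean, sd) clipped at 1 px.
* **Expression**: each cell is no-signal / X-only / Y-only / mixed. Default
  proportions (0.874 / 0.058 / 0.058 / 0.010) follow a male spinal-cord
  section's published per-cell table: ~87% silent cells, balanced X/Y,
  ~1% mixed. Expressing cells draw a zero-truncated Poisson spot count per
  expressed gene (mean 2.5 by default; mixed cells draw independently per
  gene, so they average twice the signals of a single-homolog cell — the
  published tables do not constrain how a mixed cell's total splits).
* **Space**: `ventral_x_enrichment` multiplies the X-only probability below
  the tissue bounding box's row midpoint (then renormalizes), mimicking
  ventral clustering of the X homolog while Y stays uniform; at 1 the class
  labels are exchangeable with respect to position, the basis of the type-I
  calibration test. Spots scatter isotropically (SD 3 px) around their
  nucleus, truncated at min(radius + expansion distance, half the minimum
  separation − 2 px) so the emitting nucleus is provably the nearest one and
  assignment ground truth is exact.
* **Rendering**: nuclei as filled discs, spots as Gaussian bumps (amplitude
  200, σ 1.2 px), constant background (10) plus optional Gaussian noise.
  Optional uniform false-positive spots (autofluorescent RCA-like artifacts)
  via a rate parameter; the artifact rate in real female tissue is not
  quantified anywhere, so the parameter has no calibrated default.
* **Reproducibility**: one seed per scene; placement, class sampling, spot
  scatter, false positives and render noise each use a fixed sub-stream of
  that seed, so scenes are bit-reproducible and stage-stable.

What the generator does **not** model: optical point-spread functions,
chromatic shift, uneven illumination, tissue autofluorescence texture,
segmentation-hostile nuclear clumping, or tile-stitching seams. Passing
tests on synthetic scenes therefore validate the algorithmic chain
(detection, assignment, classification, spatial statistics), not robustness
to acquisition artifacts; thresholds and top-hat radii still need per-sample
tuning on real images.

## Problem sizes in the validation suite

The acceptance computations use: four published table rows (~3.5–5k cells
each); 10,000 random profiles for the partition invariant; 100 random
256×256 scenes for the assignment oracle; 200 spots on 512×512 for KDE mass;
200 exchangeable 512×512 scenes (~1340 nuclei, ~500 spots, 100
randomizations each) for calibration; 50 enriched scenes for power; one
rendered 900×900 scene with 2000 cells for end-to-end proportion recovery;
and 1000 random homolog sets for the site finder. These sizes keep the whole
suite at desk scale while leaving each statistical check adequately powered
(e.g. the calibration rate has a binomial SD of ~1.5 points at n = 200).

## Known limitations

* Segmentation assumes separable nuclei; merged nuclei under-count cells.
* Spots closer than the top-hat scale merge into one detection; per-cell
  *categories* are robust to within-cell merging (a category needs only ≥ 1
  or ≥ 2 signals), but absolute counts per 1000 cells are biased low in
  dense clusters.
* The permutation test conditions on spot positions; it tests label
  exchangeability, not completeness of spot detection.
* Percentile CIs from 100 randomizations are coarse (resolution 1/100); the
  conservative interval errs slightly above the nominal 5% rejection rate
  (~6% under exchangeability).
* The dorsoventral border is a straight line; curved anatomical boundaries
  need external region masks.
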