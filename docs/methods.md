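# Methods

## Scope and model

The package implements the digital spatial-deconvolution analysis used to
characterise the immune microenvironment of pancreatic intraductal
oncocytic papillary neoplasms (IOPN), together with the conventional
immunohistochemistry (IHC) scoring that accompanies it.  The object of
analysis is a *phenotyped cell-coordinate map*: one record per detected
cell with micrometer coordinates, a tumor/immune/stroma class, a marker
phenotype (CD4, CD8, CD20, CD68, CD163), per-cell PD-L1 positivity, and a
tissue-component label (intraductal vs invasive).  Whole-slide imaging,
nuclear segmentation and stain chemistry are upstream of this
representation and out of scope.

The spatial model has three stages:

1. **Raster neighborhoods.**  Cells are grouped into cylindrical windows
   of fixed diameter whose centers lie on a regular grid across the ROI.
   The *composition* of a neighborhood is the vector of per-phenotype cell
   counts divided by the total cells in the window.  Default window
   diameter and grid pitch are both 200 μm — adjacent, non-overlapping
   discs.  Because the radius-vs-diameter convention of raster-window
   tooling is ambiguous, both are explicit configuration keys
   (`window_diameter_um`, `grid_pitch_um`).  Cells exactly on the disc
   boundary are counted (closed disc).  Empty windows are reported but
   excluded from clustering; the minimum-cell threshold defaults to 1 and
   is configurable.

2. **Self-organizing map (SOM).**  Composition vectors are vector-
   quantized by an online SOM: per step, one sample is drawn at random,
   its best-matching unit (BMU) found by Euclidean distance, and all node
   weights updated under a Gaussian grid-neighborhood kernel.  The kernel
   radius decays from `sigma` (default: half the larger grid dimension) to
   1 and the learning rate linearly from 0.5 to ~0.  Defaults: 8×8 grid,
   2,000 update steps (`n_iter` counts single-sample updates, the
   convention of common SOM libraries), weights initialized uniformly in
   the per-dimension data range.  Training is deterministic given the
   seed.

3. **Region selection by the Davies-Bouldin criterion.**  The SOM node
   weights are grouped into k regions by Ward agglomerative clustering
   (k-means available behind a flag) for each candidate k in 2–6, and the
   Davies-Bouldin index
   DB = (1/k) Σᵢ maxⱼ≠ᵢ (Sᵢ+Sⱼ)/Mᵢⱼ
   (Sᵢ the mean member–centroid distance, Mᵢⱼ the centroid distance) is
   evaluated **on the node weights**, matching the SOM→regions two-stage
   design; the k minimizing DB wins, ties toward the smaller k
   (parsimony).  Each neighborhood inherits its BMU's region.  Region ids
   are canonicalized by tumor content: the highest id (Re2 for k = 2) is
   the region with the highest median tumor-cell fraction, so Re1 is the
   immune-rich tumor-core-like region and Re2 the tumor-dense
   periphery-like region.  *Region extension* is the percentage of a
   component's neighborhoods assigned to a region; *region composition*
   is the per-region median of neighborhood composition vectors.

Fitting is per-case; pooled summaries are obtained by running the same
pipeline on concatenated neighborhoods.

## IHC scoring

Lymphocyte/macrophage markers are scored 0–5 from positive cells per 40×
high power field (HPF), bins closed on the right: 0; (0,10] → 1;
(10,20] → 2; (20,30] → 3; (30,50] → 4; (50,∞) → 5.  PD-1 uses the single
most positive HPF; CD3/CD4/CD8/CD20/CD68/CD163 use the mean of the five
most positive HPFs.  The **mean of counts** is binned (not the mean of
per-HPF scores): this is the only order of operations that yields a single
well-defined ordinal score.  The HPF is modeled as a circle of diameter
0.55 mm (area ≈ 0.237 mm², configurable; the field number of the source
microscope is not standardized).  `sample_hpfs` emulates the pathologist's
field choice by tiling candidate fields over the slide and ranking them by
positive count.

PD-L1: TPS = 100 × (PD-L1⁺ tumor cells)/(viable tumor cells);
CPS = 100 × (PD-L1⁺ tumor + immune cells)/(viable tumor cells), capped at
100 (standard clinical convention).  TPS ≤ min(CPS before capping) always.
MMR proteins (MLH1, PMS2, MSH2, MSH6) are called retained when ≥1% of
tumor nuclei stain (any unequivocal nuclear staining), else loss.

## Cohort statistics

The packaged 15-case cohort table carries per-case scores with
invasive-component values in separate `*_inv` columns.  Summaries mirror
the table's mean row: non-invasive values averaged, printed to one decimal
with round-half-up.  The published mean age (61.6) is the truncated value
of the column mean 61.666…; the fixture keeps raw ages and documents the
discrepancy rather than adjusting data.

Marker-vs-marker comparisons (CD3 vs CD20; CD8 vs CD4) use the **paired**
Student's t-test: the scores are paired per case, and this form reproduces
the published significance levels (CD3 vs CD20 p ≈ 5×10⁻⁷ < 0.001;
CD8 vs CD4 p ≈ 9×10⁻⁴ ≈ 0.001), which the unpaired pooled test does not
(it gives p ≈ 0.003 for CD8 vs CD4).  Component comparisons
(intraductal vs invasive neighborhood fractions) are unpaired and use the
pooled-variance Student's t by default, Welch behind a flag.  No
multiple-testing correction is applied by default; Holm adjustment is
available.

## Registration

Serial 4 μm sections shear negligibly, so the default transform model is a
similarity (rigid and full affine available).  `fit_transform` is a
least-squares landmark fit; `refine_icp` alternates nearest-neighbor
correspondence with refitting for landmark-free alignment, aborting on a
2× RMSE blow-up.  RMSE is reported per coordinate axis (so it converges to
the jitter sd under isotropic noise).  `build_composite` projects aligned
marker-positive cells onto the reference map by greedy ascending-distance
matching within a 10 μm radius (≈ one nucleus diameter); each marker cell
matches at most one reference cell and vice versa, ties break toward the
lowest cell id, and unmatched marker cells are appended as immune cells of
that phenotype.

## Synthetic tissue generator

Because no cell-level data are deposited for this tumor type, the
generator plants the structure the analysis assumes and serves as the
study condition for every end-to-end test:

* **Geometry.**  Zones are polygons; the default shorthand is a tumor-core
  disc inside a periphery annulus (core radius 1,150 μm, outer radius
  2,000 μm), matching the center/periphery architecture of these tumors.
  Zones are internally homogeneous — no within-zone density gradient is
  modeled, since no gradient is quantified for this entity.
* **Cell placement.**  Homogeneous Poisson process per zone at 1,700
  cells/mm² (epithelial tissue-scale cellularity), ~21,000 cells per
  default slide; phenotypes i.i.d. from the zone's composition vector.
* **Compositions.**  The default core and periphery vectors are the
  published median region compositions (core: tumor 44.42%, CD8 37.18%,
  CD4 13.71%, CD20 4.69%; periphery: tumor 89.43%, CD8 7.50%, CD4 2.54%,
  CD20 0.54%, renormalized to the simplex).  The two-component case plants
  a proportionally smaller core in the invasive component (radius 800 vs
  1,150 μm) and a strong CD4-down/CD8-up shift (core CD8 0.50, periphery
  CD8 0.18; CD4 0.05/0.010), consistent with the large ordinal score
  shifts observed in invasive components (CD4 3–4 → 2, CD8 3–4 → 5).
* **PD-L1 / macrophages.**  PD-L1 positivity is a position-independent
  per-cell Bernoulli flag (tumor and immune probabilities in the spec),
  since only slide-level TPS/CPS are reported for this entity.  CD68/CD163
  co-positivity ("almost superimposable" staining) is modeled as a
  macrophage co-expression flag with probability 0.95.
* **Serial sections.**  A planted similarity transform plus isotropic
  Gaussian jitter (default sd 3 μm) and random dropout (default 20%),
  emulating section-to-section cell loss.
* **Randomness.**  One root seed; child streams spawned in a fixed order
  (zone placement streams, zone phenotype streams, PD-L1, co-expression,
  serial section), so every artifact is reproducible from (spec, seed).

What the generator does **not** emulate: irregular tumor outlines,
within-zone density gradients, segmentation errors, staining artefacts,
or spatial clustering of immune cells beyond zone membership.  Passing
tests therefore demonstrate that the pipeline recovers planted structure
of the reported kind at realistic sample sizes — not that it would be
robust to every artefact of real slides.

## Numerical choices and degenerate inputs

* Davies-Bouldin raises for <2 clusters or fully coincident centroids and
  returns +inf when some (not all) centroid pairs coincide.
* Composition is undefined (raises) for empty neighborhoods; empty windows
  never reach clustering.
* `bin_count` accepts non-integer counts (means); negative counts raise.
* `mean_top5` with <5 HPFs falls back to all fields with a warning.
* TPS/CPS raise on a zero tumor-cell denominator; TPS warns under 100
  viable tumor cells.
* Zero-area zones raise; a zone whose expected count is <1 warns and may
  be empty.
* Degenerate (collinear/duplicate) correspondence sets raise in
  `fit_transform`; empty clouds raise in ICP.

## Problem sizes

Default end-to-end runs use ~21,000 cells / ~310 populated neighborhoods
(single component) and ~42,000 cells / ~620 neighborhoods (two-component
case); at these sizes the full pipeline completes in seconds and planted
compositions are recovered to well under one percentage point per zone,
so the acceptance tolerances are dominated by sampling noise of
per-neighborhood medians, not by the optimizer.

## Known limitations

* The SOM is an online (sample-at-a-time) implementation; batch training
  is not provided.
* ROI dialect support covers the common QuPath GeoJSON export
  (FeatureCollection of Polygon features); exotic geometry types are not
  handled.
* The exact numerics of the original raster/SOM tooling are not
  reproduced; agreement is claimed at the level of recovered structure
  (region count, median compositions, extension ordering), not per-run
  equality.
* Per-slide positivity thresholds for DAB intensity are exposed but not
  calibrated; synthetic tests use planted boolean flags.
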