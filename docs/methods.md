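# Methods

## Scope and model

`fibroquant` turns a collagen-stained brightfield biopsy image into a
per-biopsy vector of quantitative fibrosis traits (qFTs) and continuous
composite severity scores, and analyses cohorts of such biopsies for
intra-liver sampling variability (CoV) and stage discrimination (AUROC).
The pipeline assumes:

* Beer–Lambert imaging: pixel optical density `OD = −ln(I/255)` is a
  non-negative combination of two stain absorption vectors (collagen
  stain + counterstain).  Two palettes are built in — Masson's trichrome
  (blue-green collagen / red counterstain) and Picro-Sirius red (red
  collagen / yellow counterstain).
* Collagen is colour-separable from counterstained tissue after stain
  normalisation; fibrosis "fibres" are connected components of the
  thresholded collagen-stain channel.
* One biopsy is analysed independently of all others; cohort statistics
  only combine per-biopsy outputs.

## Stage-by-stage choices

**Colour normalisation.**  Stain vectors are estimated per image in the
Macenko style: SVD plane of tissue-pixel ODs, 1st/99th-percentile extreme
angles, matched to the palette's reference profile by cosine similarity;
pixel concentrations are obtained by non-negative least squares and
re-rendered with the reference vectors.  Concentrations are not
percentile-rescaled, which makes the operation idempotent and an exact
identity on images already in the reference basis (both properties are
tested).  Degenerate (blank or single-valued) images raise a dedicated
error.

**Tissue detection.**  Background is "all three channels above 90 % of
white"; holes are filled, fragments below `min_fragment_area_um2`
(default 500 µm²) are discarded, fragments are labelled with
8-connectivity.  No stripe/dust detector is included (the synthetic data
have none); saturated-pixel handling reduces to the white threshold.

**ROI.**  The analysis region is tissue eroded by `margin_um`
(default 50 µm), implemented by thresholding the exact Euclidean
distance transform at `round(margin_um/mpp)` px — equivalent to erosion
by a Euclidean disk, and exact on rectangles (a 400×400 px square at
0.5 µm/px erodes to exactly 200×200).  Fragments that erode away are
dropped with a warning.

**Non-contributory fragments.**  A fragment whose collagen fraction
strictly exceeds `fibrosis_fraction_cutoff` (default 0.90) — detached
capsule or sheared septa — is removed and logged; exactly 90 % is
retained.  The rule runs on a provisional whole-tissue collagen
segmentation before the ROI is fixed.  Operator visual review of the
original workflow is replaced by machine-readable removal reports.

**Collagen segmentation.**  Otsu threshold on the collagen-stain
concentration within the ROI, with a floor of 0.2 concentration units so
collagen-free biopsies yield empty masks instead of noise; objects under
`min_fibre_area_um2` (default 25 µm²) are removed.

**Fibres and branching.**  Fibres are 8-connected components, ordered by
descending area (ties: top-left pixel, row-major).  Skeletons come from
topology-preserving thinning; before counting, the skeleton is re-thinned
and spurs shorter than 3 px ending at junctions are pruned.  A *branch
point* is an 8-connected cluster of skeleton pixels with ≥ 3 skeleton
neighbours (clustering is what makes a '+' crossing one branch point
rather than five); an *endpoint* has exactly one neighbour (an isolated
pixel counts as one endpoint).  Fibres with more than 21 branch points
are *assembled*, the rest *fine*; the boundary value 21 is assigned to
fine, a documented choice where the classing rule's strict inequalities
leave the tie open, and the cutoff is configurable.

**Trait registry (version `fq-registry-1.0`).**  The exact trait lists
of commercial phenotypic platforms are proprietary; this registry is an
explicit stand-in with the same layer structure and counts:

* morphometry, 13 per fibre: area, perimeter, skeleton length, mean
  width (area/skeleton length), max/min Feret (convex hull of pixel
  corners; min by rotating calipers), aspect ratio, circularity
  (4πA/P²), solidity, eccentricity, tortuosity (skeleton length / max
  Feret), branch count, endpoint count.  Zero-skeleton fibres fall back
  to tortuosity 1 and width √A, flagged.
* deposition, 12: per fibre, five OD statistics + integrated OD + ROI
  coverage; per slide, CPA, fibre density (fibres/mm²), assembled and
  fine area fractions, mean nearest-fibre centroid distance.
* architecture, 7 per tile: GLCM entropy (base-2), contrast,
  homogeneity, energy, correlation, dissimilarity, cluster shade,
  averaged over offsets.  Defaults: 32 grey levels quantised against the
  ROI's 99.5th-percentile OD, distance 2 px, angles 0/45/90/135°,
  symmetric and normalised, 256×256 px tiles kept at ≥ 50 % ROI
  coverage.  A fixed tile grid is used for determinism; tests and the
  desk-scale experiments use 64×64 px tiles because the synthetic
  canvases are only a few hundred pixels across.  Constant tiles have
  correlation defined as 0 with a flag.  Texture is computed on the
  collagen OD channel (not the raw image) so that it describes fibrosis
  architecture rather than counterstain layout.

**qFTs.**  Every per-fibre trait is summarised over three populations
(all / assembled / fine) and every architecture trait over tiles by five
histogram statistics: mean, median, population SD (denominator *n* — the
convention that reproduces the published summary tables, see below),
Fisher–Pearson g1 skewness and excess kurtosis g2.  Fewer than 3 values
or zero variance give flagged zeros for g1/g2; an empty population gives
flagged *missing* (NaN) statistics, never zeros.  Slide-level deposition
traits enter as-is.  The default registry yields
(13+7)×3×5 + 7×5 + 5 = 340 named parameters; the manifest reports the
count rather than hard-coding any particular published total, since the
composition scheme reaching a specific commercial count is not public.

**Composite scores.**  Between a less-severe group A and a more-severe
group B, a qFT is *principal* when its relative mean change
|mB−mA|/max(|mA|, ε) is ≥ 20 % and its two-group test (Welch t by
default, Mann–Whitney optional) gives p < 0.05.  Eligibility requires
≥ 3 non-missing biopsies and ≥ 90 % completeness per group: statistics
of populations that are often absent (e.g. assembled-fibre traits in
mild biopsies) cannot anchor a score meant to apply cohort-wide.  No
multiple-testing correction is applied by default — principal-qFT counts
in this biomarker family imply per-test thresholds — with an optional
Benjamini–Hochberg switch.  Fitting stores each selected qFT's
2.5th/97.5th fitting-cohort percentiles as clipped min–max bounds
(robust to outliers) and the sign of the group shift; scoring maps each
qFT to [0,1], flips decreasing qFTs, averages with equal weights and
scales to (0, 10) — a scale chosen to match the magnitudes this
biomarker family displays; the published normalisation and scale are not
stated.  Scores are bounded by the output scale and monotone in every
selected qFT.  Up to 20 % missing selected qFTs are tolerated with
renormalised weights and a flag; more raises an error.

**Cohort analysis.**  CoV = 100·σ/μ with population σ.  The convention
was fixed *before* implementation by brute-force comparison against the
published 20-patient summary rows: the printed SDs (5.6 for the
composite CoV row, 11.9 for the CPA CoV row) match the population
formula (5.59, 11.94), not the sample formula (5.74, 12.25).  CoV
classes: < 15 % low, 15–30 % moderate (both boundaries inclusive),
> 30 % high.  AUROC uses the rank (Mann–Whitney U) estimator with ties
counted ½ and a class-stratified percentile bootstrap CI (2000
replicates, seeded).  Group comparisons: two-sided Welch t by default.

## Synthetic histology generator

The generator emulates what the pipeline must discriminate, not what a
pathologist sees; nuclei, steatosis, inflammation and pyramidal WSI
structure are out of scope.

* **Tissue**: `n_fragments` elongated fragments with smooth calibre
  variation and tapered ends, separated by ≥ 8 px, mimicking a
  fragmented 14-gauge core at desk scale (default canvas 512×256 px at
  2 µm/px; the cohort experiments use 768×320 px).
* **Septa**: ridges of a jittered Voronoi tessellation.  Cell pitch is
  `nodule_diameter_um` (default 120 µm, a deliberately scaled-down
  nodule so that a desk-scale canvas contains a full septa network)
  shrunk further as severity rises — mild disease has large nodules and
  sparse thin septa, severe disease small nodules ringed by widespread
  thick septa.  Septa half-width grows linearly with severity (zero at
  severity 0, which keeps severity-0 biopsies under 3 % collagen) and is
  capped at half the pitch so nodules never fully collagenise.
* **Fine fibrils**: a fixed candidate pool of 400 short random-walk
  fibrils per image, of which the first `severity × 400` are drawn —
  nesting the pool guarantees strictly monotone collagen masks in
  severity.  Fibrils are placed inside nodules, clear of the septa, so
  they remain individually resolvable fine fibres.
* **Load nuisance**: a per-biopsy mean-one lognormal factor with
  relative SD `load_jitter` (default 0.35) multiplies the apparent septa
  width, emulating the staining-depth and section-thickness variability
  that dominates the sampling CoV of area-ratio biomarkers.  The default
  magnitude was chosen to place intra-liver CPA CoVs in the 25–45 %
  band reported for multi-segment explant cohorts by image-analysis
  methods.
* **Rendering**: pure Beer–Lambert with the palette's reference
  vectors; collagen pixels carry only collagen stain (making stain
  estimation exact on noise-free images), tissue pixels carry
  counterstain at concentration 0.35; optional per-image affine stain
  jitter and additive Gaussian RGB noise.  Identical parameters
  (including seed) are bit-reproducible.
* **Cohorts**: livers receive evenly spaced base severities over an
  optional range; within a liver, biopsy severities are multiplicative
  perturbations with relative SD `heterogeneity` (the spatial
  heterogeneity of cirrhosis across segments).

What passing tests on these images *do* show: the pipeline's geometry,
colour handling, statistics and score construction are correct, and the
qualitative phenomena — composite continuity with severity, composite
CoV below CPA CoV — emerge from the mechanism, not from tuned constants.
What they do *not* show: performance on real histology, where stain
overlap, necrosis, inflammation and scanner artefacts violate the
two-stain colour-separability assumption to varying degrees.

## Desk-scale experiment design

The acceptance experiments are sized for a single CPU in minutes:

* segmentation fidelity on one noise-free 512×256 biopsy (tissue Dice
  ≥ 0.99, collagen Dice ≥ 0.95) and exact fragment counts at ≥ 5 px
  separation;
* selection recovery at the matrix level: 10 planted 30 %-shift qFTs
  (CV 10 %, n = 20/20) among 30 nulls, plus 10 %-shift decoys with tiny
  variance that must fail the 20 % rule despite p ≈ 0; five Monte-Carlo
  replicates;
* a 60-biopsy cohort (12 livers × 5 segments, 768×320 px, planted
  severity 0.1–0.9, heterogeneity 0.15, full stain/noise/load nuisance)
  analysed end-to-end; the composite is fitted between the severity
  tertiles and evaluated by Spearman ρ against planted severity, tertile
  AUROC with bootstrap CI, and per-liver CoV against CPA.

## Known limitations

* The trait registry is a documented stand-in; absolute qFT values are
  not comparable to any proprietary platform's.
* Min-Feret/rotating-calipers and perimeter estimates carry the usual
  digitisation bias for objects a few pixels wide.
* The >90 %-fibrosis rule is the only automated surrogate for operator
  artefact review; perivascular structures are not specifically
  modelled.
* Stain estimation needs both stain classes present in reasonable
  abundance; near-collagen-free images fall back to thresholding
  behaviour guarded by the concentration floor.
* The Voronoi-ridge septa model has no explicit bridging fibrosis stage
  and no portal-tract anatomy; heterogeneity acts on severity and load
  only, not on fragment geometry.
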