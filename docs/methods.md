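# Methods

## Problem and scope

`immunomargin` implements a quantitative-pathology workflow for resected
hepatocellular carcinoma: estimate the areal density of T- and
B-lymphocyte profiles (CD3+, CD8+, CD20+) in five tissue compartments,
derive prognostic features from those densities, and test their
association with time to recurrence (TTR), disease-free survival (DFS)
and overall survival (OS). Because no patient-level data are published
for the cohort this emulates, the package ships a synthetic-data module
that states the world the analysis assumes; every downstream stage is
exercised end-to-end on that world.

## Regions of interest

A tissue section is a calibrated integer label mask (background,
non-tumor liver, tumor). The tumor border is the set of tumor pixels
4-adjacent to non-tumor liver. Bands are built from the Euclidean
distance (on pixel centers) to that border:

* **innM** — tumor pixels within 500 µm of the border,
* **TC** — the remaining tumor,
* **outM** — liver pixels within 500 µm,
* **PT** — liver pixels at distance in (500, 1000] µm,
* **NT** — a separate, distant liver-only section, attached verbatim.

Pixels exactly at a band boundary belong to the band nearer the border
(closed upper bound). `band_width = 0` is treated as the degenerate
no-margin case (TC = tumor, empty bands) rather than applying the closed
bound to the border pixels themselves. A simulated fibrous capsule is
part of the non-tumor side: distance is measured from the malignant-cell
border. On a disc tumor of radius 2000 µm the band areas converge to the
analytic annuli as the pixel size shrinks (≤ 2% error at 5–10 µm; tested
at 20, 10 and 5 µm).

## Stereological density estimation

Q_A = (counted profiles) / (total counting-frame area), reported per
mm². Fields of view are selected by systematic uniform random sampling:
FOV-sized grid cells over the ROI bounding box are enumerated in raster
order, cells intersecting the ROI are candidates, and one uniform random
start plus every ⌈N/n⌉-th candidate gives the n = 8 fields. Frames are
laid on a fixed grid inside each FOV, top-left first, and **only frame
slots whose full pixel footprint lies inside the ROI are eligible** —
this keeps the area denominator honest, which is what makes the
estimator unbiased for a homogeneous point process (verified to < 3%
over 500 sampling replicates at λ = 200/mm²).

Counting follows the forbidden-line rule. For centroid data the classic
frame with exclusion-line extensions collapses to a half-open rectangle:
count a point iff `x ∈ (x0, x0+w]` and `y ∈ (y0, y0+h]` — left and
bottom edges excluded, right and top included. This tiles the plane, so
no centroid can be counted twice by adjacent frames.

Designs per ROI mirror the staining protocol: inner/outer margin 6
frames × 8 FOV totalling 417,611 µm² (≈ 8700 µm² per frame); peritumor 9
frames × 8 FOV totalling 417,215 µm² (10× objective, so only the FOV is
larger); tumor center and non-tumor liver adapt the frame area on the
ladder 8700–34,801 µm² so that the expected count per frame reaches 2
(smallest adequate frame; empty regions get the largest), with 6–9
frames per image (more small frames, fewer large ones, capped by what
fits in the FOV). The sparsest regions therefore get the largest total
sampled area. The "total area per probe" figures are interpreted as
totals over all 8 FOVs of an ROI; the per-image reading is available by
configuring `SamplingDesign` directly.

Cell "profiles" are input centroids: the microscopic nucleated/mid-portion
transection rule is assumed already applied by the upstream detector or
by the simulator. Degenerate ROIs (smaller than one FOV, or too few
candidate fields) fall back to fewer or centered fields with explicit
warnings carried into the results.

## Synthetic world

**Tissue.** A disc / ellipse / perturbed-blob tumor rasterized in liver,
with ≥ 1100 µm clearance to the image edge so that outer margin and PT
band exist. Points are homogeneous Poisson per ROI: a mask pixel is
drawn uniformly, then the point is placed uniformly within the pixel —
exact for raster-defined regions.

**Intensities.** Defaults (profiles/mm²):

| marker | TC | innM | outM | PT | NT |
|--------|----|------|------|----|----|
| CD3 | 200 | 360 | 1000 | 1300 | 400 |
| CD8 | 100 | 210 | 600 | 800 | 250 |
| CD20 | 10 | 23 | 200 | 260 | 40 |

The inner/outer and TC/outer ratios are anchored to the reported cohort
median ratios (≈ 0.36/0.35/0.11 and 0.20/0.17/0.05 for CD3/CD8/CD20);
PT is set to 1.3 × outM (the gradient peaks in PT but PT and outM are
close); B-cell densities sit an order of magnitude below T-cells.

**Patient heterogeneity.** λᵢ(m, r) = base(m, r) · Lᵢ · exp(ε). Lᵢ is a
lognormal(0, 0.6) immune level shared across markers and ROIs (this
alone reproduces strong inter-marker correlations). The log-noise ε is
structured: liver-side ROIs (outM, PT, NT) get independent N(0, 0.7²);
the tumor-side ROIs (TC, innM) share a per-(patient, marker)
"penetration" component g ~ N(0, 0.67²) plus N(0, 0.2²) residual. Every
pairwise log-ratio then has σ ≈ 0.99, which puts the CD20 inner/outer
ratio below 0.1 in ≈ 45% of patients (reported: 46%) versus ≈ 10% for
CD3/CD8 (reported: 9% and 13%), while g makes the penetration ratio
correlate with tumor-center density at ρ ≈ 0.3–0.5 (reported:
0.47–0.63). These fractions and correlations were fixed from the
published summary statistics before any acceptance measurement and are
not tuned.

**Outcomes.** Proportional hazards with Weibull baseline H₀(t) =
(rate·t)^shape (shape 1 = exponential, months). The hazard-driving
immune score is log Lᵢ plus the mean penetration component; patients
above the population median form the "high" group with default
recurrence HR 0.3 (within the 0.09–0.6 range of the reported
inner-margin effects). Recurrence and death are two correlated
processes (Gaussian copula, ρ = 0.3 by default — no joint
recurrence–death model is established for such cohorts, so the
correlation is an explicit free parameter); administrative censoring is
uniform on (0, 240) months.
Baseline rates (0.02 and 0.0085 per month) are calibrated so that ≈ 40%
of patients show observed recurrence and ≈ 57% die under observation,
and the inverse-KM median follow-up lands near 100 months — the event
mix of the emulated cohort. Observed recurrence ≤ death holds by
construction; endpoints are then *derived* from the observed triple by
the endpoint rules, keeping that logic independently testable.

**What a green test does not establish.** The generator produces
circularly-symmetric tumors, homogeneous Poisson infiltrates and
marker-independent penetration noise. Real sections have anisotropic
margins, clustered (often peri-stromal) lymphocytes, staining artifacts
and detection error; unbiasedness under clustering, and robustness to
segmentation error, are not claimed.

## Prognostic features

Percentile categories use average-rank percentiles, `rank/n·100`: low
< 25, intermediate in the closed interval [25, 70], high > 70 (the outer
categories are defined by strict inequalities, so the boundary
percentiles belong to the middle). The two-level variant merges
intermediate+high at the 25th percentile. Inter-ROI ratios
(innM/outM, TC/outM, TC/M, TC/PT) use raw Q_A; the entire margin M
pools raw counts over both bands' frame areas. Ratios are dichotomized
at the cohort median with strict ">" for above-median (ties go under);
the median is stored for audit. A ratio with a zero or missing
denominator is missing, and missingness propagates — nothing is
imputed. The immune-excluded phenotype is an inner/outer margin ratio
< 0.1. The combined CD8/CD20 group is the 2×2 of the two-level
inner-margin categories.

## Survival statistics

Endpoints: TTR = (recurrence, 1) or censored at death/last follow-up;
DFS = first of recurrence/death; OS = death or censored. DFS time is
always min(TTR time, OS time).

Kaplan-Meier, log-rank, Cox and reverse-KM go through lifelines; group
tests through scipy. Cox fits use the Efron tie approximation (the
source software is unstated; Efron is the better default at the tie
rates synthetic data produces). Categorical factors are dummy-coded
against "low"/"under-median"; each non-reference level gets an HR with
95% Wald CI, and the whole factor a type-3 Wald test (joint test of its
coefficient block). Multivariable models force age and TNM stage, fit
one model per immune feature (screened at univariable p < 0.05), and
backward-eliminate any other term at p ≥ 0.05; forced covariates and
the focal feature are never dropped. Median follow-up is the median of
the KM curve with censoring indicators flipped.

Degenerate fits are flagged, never silently numeric: a factor level
with zero events (monotone likelihood), non-convergence, or a standard
error above 10 (separation) yields a flagged result rendered as
"NA (reason)" in reports. Friedman across ≥ 3 matched regions (the
2-region case reduces to the paired sign test); pairwise Wilcoxon
signed-rank p-values are Bonferroni-multiplied and capped at 1.

A caveat demonstrated during development: with the default copula
correlation, death is *dependent* censoring for TTR, and the TTR Cox
estimate acquires a genuine ≈ −0.09 log-HR bias at n = 1000. Parameter
recovery (coverage and bias) is therefore validated with the
correlation at 0; the realistic world keeps 0.3 and inherits the bias
real TTR analyses also carry.

## Numerical and design choices

* Distances and coordinates: 0-based pixel indices; physical coordinate
  of a pixel = index (+ offset within pixel) × pixel size; distance
  transform on pixel centers (scipy EDT).
* Randomness: one master seed; every stage draws from a named substream
  (`substream(seed, "points", patient, marker)` etc.), so runs
  reproduce bit-for-bit and stages are insensitive to each other's
  draw counts.
* Adaptive frame target count: 2 expected profiles per frame — small
  enough to keep the smallest frames in dense tissue, large enough that
  sparse regions are not all zeros.
* Time unit months; 95% CIs everywhere; two-sided p < 0.05.
* The percentile boundary convention (middle interval closed) follows
  from the strict "below/above" wording of the category definitions;
  cohort percentiles are computed on the values available per feature
  after exclusions.

## Known limitations

* No pixel-level cell detection or stain simulation; detections are
  inputs.
* No competing-risk or time-varying Cox models; the dependent-censoring
  bias above is documented, not corrected.
* NT comes from a separate block, so cross-section registration is out
  of scope; NT simply carries its own grid.
* The report tables list many correlated features without multiplicity
  correction across features (matching the emulated analysis design);
  interpret isolated significant p-values accordingly.
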