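# immunomargin

Stereological profiling of T- and B-lymphocyte infiltration across the
invasive margin of resected liver tumors, with survival association.

## The problem

In hepatocellular carcinoma, where tumor-infiltrating lymphocytes sit
matters as much as how many there are: cells that mass at the tumor
border but fail to penetrate it (the *immune-excluded* phenotype) carry
a different prognosis than cells inside the tumor. This package
implements the quantitative workflow for that question, aimed at
quantitative pathology and biostatistics users:

1. **ROI geometry** — partition a calibrated tissue label mask into
   tumor center (TC), inner and outer invasive margin (innM/outM, the
   500 µm bands on each side of the tumor border), peritumor liver (PT,
   the next 500 µm) and a distant non-tumor block (NT), via a Euclidean
   distance transform from the malignant border.
2. **Stereology** — estimate Q_A, the areal density of immunopositive
   nucleated cell profiles, with systematic uniform random sampling of
   fields of view and 2D unbiased counting frames:

   Q_A = Q⁻ / ΣA(frames) × 10⁶  [profiles/mm²]

   where Q⁻ counts centroids under the forbidden-line rule (left/bottom
   frame edges exclude, right/top accept).
3. **Scoring** — rank-percentile categories (low < 25th, intermediate
   25th–70th, high > 70th), inter-ROI ratios of raw Q_A dichotomized at
   the cohort median, the pooled entire-margin density, immune-excluded
   flags (innM/outM < 0.1) and combined CD8/CD20 inner-margin groups.
4. **Survival** — TTR/DFS/OS endpoint construction, Kaplan–Meier and
   log-rank, univariable Cox per feature (per-level HRs with 95% CI and
   a type-3 Wald factor test), age/TNM-adjusted multivariable Cox with
   backward elimination, inverse-KM median follow-up, Friedman/Wilcoxon
   region comparisons and Spearman correlations.
5. **Synthetic data** — calibrated synthetic sections (marked Poisson
   point processes over the ROI partition) and patient cohorts with a
   proportional-hazards outcome model, so the entire pipeline is
   testable without patient data. See `docs/methods.md` for the stated
   world and its anchoring.

## Worked example

The `analysis/` scripts run the study end to end on a 60-patient
synthetic cohort (`--seed 1`):

```bash
python analysis/01_simulate_study.py --seed 1   # sections, detections, cohort
python analysis/02_partition_rois.py            # band areas vs analytic annuli
python analysis/03_estimate_densities.py        # stereological Q_A + gradient
python analysis/04_score_features.py            # prognostic features
python analysis/05_survival_analysis.py         # Cox/KM association tables
```

Band partition of the disc-tumor section (script 02):

```
 roi  area_mm2  analytic_mm2  rel_error_pct
  TC    3.0920        3.1416          -1.58
innM    3.9768        3.9270           1.27
outM    5.4788        5.4978          -0.35
  PT    7.0696        7.0686           0.01
```

The 500 µm bands recovered from the raster mask match the analytic
annuli of the simulated tumor to within ~1.6% at 10 µm pixels.

Cohort median Q_A per marker and ROI (script 03):

```
roi        TC   innM    outM      PT     NT
CD20     11.8   25.5   220.2   267.3   37.6
CD3     230.7  469.8  1308.7  1426.2  441.5
CD8      93.9  226.0   652.1   812.1  256.3
```

Density falls from peritumor liver through the outer and inner margin
into the tumor center, B-cells sit an order of magnitude below T-cells,
and the inner margin is significantly sparser than the outer (Wilcoxon,
Bonferroni-corrected p < 1e-5 for every marker). Scoring (script 04)
reports the immune-excluded phenotype in 55% of patients for CD20
against 8–10% for T-cells, with inner/outer median ratios 0.353 (CD3),
0.326 (CD8) and 0.120 (CD20). The survival stage (script 05) prints a
median follow-up of 102 months (inverse KM) and finds high CD8 density
in the inner margin protective for recurrence (HR 0.19, 95% CI
0.04–0.97) — at n = 60 most other features are directionally protective
but not individually significant, the expected behavior of a small
cohort.

The same run is available as one command:

```bash
immunomargin all --seed 1 --out runs/r1
```

which writes the density table, feature table, three report tables
(per-ROI categories, median-split ratios, adjusted models), KM/follow-up
summaries and a manifest recording the seed and config hash; rerunning
with the same seed reproduces every stochastic stage bit-for-bit.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch at the given seed —
synthetic study, band partition, stereological counting, scoring and
survival association — prints the cohort density summary, and writes the
results JSON.
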