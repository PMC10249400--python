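# Methods

## Scope and model

The pipeline estimates, per freshwater region, a species sensitivity
distribution (SSD) of fish against total nitrogen concentration and converts
it into gridded effect factors (EFs) for life-cycle impact assessment. The
core assumptions are:

1. **Tolerance-by-observation.** A species tolerates nitrogen up to the
   highest concentration at which it has been observed in a region. The
   threshold is the maximum over occurrences matched to the concentration of
   the same 0.5° pixel and year. Only the upper threshold is modeled; a lower
   (nutrient-starvation) threshold is deliberately out of scope, consistent
   with current LCIA practice.
2. **Survivor counting.** With thresholds `T_1..T_n` in region *i*, the
   response at level `C_j` (the sorted unique thresholds) is
   `PDF_ij = 1 − SR_ij / SR_i,max`, where `SR_ij = #{s : T_s ≥ C_j}`. The PDF
   at the smallest level is therefore 0 and values lie on the grid
   `{0, 1/n, …, (n−1)/n}`.
3. **Logistic SSD on untransformed concentration.**
   `PDF(C) = 1/(1 + exp(−(C − a)/b))`, so `a` is directly the concentration
   (mg/L) at which half the species pool has disappeared and `b` (mg/L) the
   slope coefficient. A switch (`transform_points_log10`,
   `fit_all_regions(log_concentration=True)`) refits on log10(C) for
   sensitivity analysis; it is off by default because the location coefficient
   is defined on the concentration scale.
4. **Unweighted least squares.** `(a, b)` minimize the sum of squared
   residuals over the PDF–concentration pairs; points are not weighted by
   richness. Regions with ≤3 pairs are `insufficient_data`; optimizer
   non-convergence is recorded as `failed`, never raised, so batch fitting
   always completes.
5. **Hierarchy.** SSDs are fitted independently at the ecoregion level and at
   the coarser realm–major-habitat-type (realm-MHT) level, the latter by
   re-pooling matched occurrences under the coarser raster (not by
   aggregating ecoregion thresholds). EFs use the ecoregion SSD when it is
   fitted *and* good; otherwise they fall back to the realm-MHT SSD; if
   neither is usable the cell has no value. Treating failed/poor ecoregion
   fits as "insufficient" for fallback purposes is a robustness choice: a
   demonstrably bad regression should not block a usable coarser one.

## Diagnostics

The Cox–Snell pseudo-R² is computed as `1 − (L0/L1)^(2/n)` with Gaussian
likelihoods whose variance is the maximum-likelihood residual variance; this
reduces algebraically to `1 − RSS_fit/RSS_null` with the intercept-only (mean
PDF) null, which is how it is evaluated (the identity is asserted in tests
against explicit likelihoods). It is undefined when all observed PDFs are
equal. NRMSE is the root-mean-square residual divided by the mean observed
PDF, undefined when that mean is 0 (single-threshold regions). The good-fit
flag is `pseudo-R² > 0.5 and NRMSE < 1`; poor fits are flagged, not deleted —
only the EF stage refuses them.

## Effect factors

`EF_marginal = 1000 · PDF(C)·(1−PDF(C))/b` at the current-state (2010)
concentration; `EF_average = 1000 · (PDF(C_cur) − PDF(C_ref))/(C_cur − C_ref)`
against the 1900 reference field. The 1000 converts the reciprocal
concentration from L/mg to m³/kg, and is applied as a multiplication of the
raw derivative so the unit identity holds exactly in floating point. When
`|C_cur − C_ref| < 1e-12` mg/L the analytic limit — the marginal EF — is
returned rather than a missing value. Note that for a strictly increasing
SSD the average-EF secant is positive regardless of which state is larger
(numerator and denominator share signs); a negative average EF cannot occur
under this model. Cells with current concentration below the zero cutoff
(1e-4 mg/L, the measurement/modeling uncertainty floor) carry no EF with
reason `zero_N`; cells without a usable SSD at either level carry reason
`no_ssd`; a missing reference concentration leaves only the average EF
undefined (`undefined_ref`). The three cases are encoded distinctly rather
than collapsed into one "no value" convention.

## Synthetic world

The generator replaces the study-scale inputs (multi-database occurrence
compilations and global nutrient-model output) with a world whose truth is
known:

* Per region, thresholds are inverse-CDF logistic draws
  `T = a + b·ln(u/(1−u))`, redrawn while `T ≤ 0`. Conditional on positivity
  the law stays logistic; with the default `a ≫ b` the truncated mass is
  1–2%, visible as a ≲10% downward bias in recovered `b` at small samples.
* Every species is pinned to one distinct pixel-year inside its region's
  rectangular block whose concentration equals its threshold exactly, so the
  max-of-matched rule recovers the truth to machine precision when the
  optional relative jitter (default 0) is off. Extra sightings (Poisson, mean
  2 per species) land only on pixel-years with concentration ≤ the threshold.
  Remaining block pixel-years are filled with draws from the same truncated
  logistic.
* 10% of species are emitted under a synonym resolvable via the synonym
  table, and 10% of records are duplicated with the year or the coordinates
  blanked, to exercise harmonization and filtering.
* Cells outside all blocks hold 5e-5 mg/L (below the zero cutoff); the 1900
  reference field holds 0.01 mg/L inside blocks.

Defaults (`default_world_config`): a 60×120-cell domain at 0.5°, window
1970–2010 with reference year 1900, four ecoregions of 200 species in two
realm-MHT units, true `(a, b)` of (1.5, 0.4), (2.5, 0.6), (4.0, 1.0) and
(8.0, 2.0) mg/L — locations spanning the low-mg/L range typical of fitted
nitrogen SSDs, with `a/b ≈ 4` so truncation distortion stays small.

What the generator does **not** emulate: real fish biogeography and range
shapes, spatial/temporal autocorrelation of nutrient fields, sampling effort
bias, taxonomic error beyond exact-string synonyms, and concentration
measurement error (thresholds are placed exactly). Passing tests therefore
demonstrate correctness of the algorithms and statistical recovery under the
stated sampling law — not that real occurrence data meet these assumptions.

## Numerical choices

* Grid convention: origin at (−180°, +90°), row-major; cell `(r, c)` covers
  `lat ∈ [90 − 0.5(r+1), 90 − 0.5r)`, `lon ∈ [−180 + 0.5c, −180 + 0.5(c+1))`;
  points exactly on the +90°/+180° edges clamp to the nearest valid cell.
* Fit initialization: `a0` = level whose observed PDF is nearest 0.5,
  `b0` = (max level − min level)/4, bounds `b ≥ 1e-9`, `a` unconstrained;
  robust for monotone step data. Tight `xtol/ftol/gtol` (1e-14) so the
  optimum matches a dense grid search within lattice resolution.
* Deduplication key is (accepted name, year, cell): exposure matching is
  pixel-year resolved, so finer duplicates are information-free; first record
  in input order wins, making the stage stable and idempotent.
* Unmatched raw names are kept as their own accepted name, never dropped.
* All tabular artifacts use fixed column order and `\n` line endings;
  rasters are classic NetCDF written through xarray's scipy engine — reruns
  with the same seed are byte-identical.

## Problem sizes

The bundled analyses and tests run on deliberately desk-scale worlds: the
default world has 800 species on a 60×120 grid (≈2 600 records); the
parameter-recovery study uses 20 replicates of a 500-species region on a
16×16 grid; the zero-cutoff check runs on a full 360×720 global grid. These
sizes give tight recovery (location within ~3%, slope within ~10%) while the
entire suite completes in well under a minute.

## Known limitations

* Single concentration value per pixel-year; whether an annual mean or
  another temporal statistic is used upstream is the caller's choice.
* No bootstrap or other uncertainty on `(a, b)`; no alternative SSD forms
  (log-normal, Burr III); no lower-tolerance (hump-shaped) responses.
* Species–region assignment is purely raster-based via the occurrence cell;
  no range polygons.
* EFs are the effect component only — fate and exposure factors, and hence
  full characterization factors, are out of scope.
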