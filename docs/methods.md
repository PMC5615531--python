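# Methods

This note documents the statistical and geospatial procedures implemented in
`geovuln`, the assumptions behind them, the defaults and why, and what the
synthetic-data generator does and does not emulate.

## Outcome and risk model

The outcome is a binary depression-case indicator defined by the 15-item
Geriatric Depression Scale with the Asian-population cutoff, GDS-15 ≥ 8.
Risk is modelled as a binomial logistic regression of the case indicator on
five social vulnerability indicators (age ≥ 80, male, not married, low
education, living alone), four built-environment measures (% residential
area, % vegetation, and the percentile-normalised mean and standard
deviation of building height in a 400-m buffer), and six lifestyle/medical
confounders (dementia, physical-activity score, cardiovascular disease,
respiratory disease, alcohol, smoking). Model 1 drops the environmental
block, Model 2 drops the social block, Model 3 keeps both; confounders are
always present. Complete-case analysis: any row with a missing analysis
variable is removed before fitting, and the count is reported.

The fit is by iteratively reweighted least squares, written here rather
than delegated, because the fitting engine is part of what the package
exists to provide and to test. Numerical choices:

* Newton/IRLS steps with step-halving (up to 30 halvings), which makes the
  Bernoulli log-likelihood non-decreasing across iterations; the trajectory
  is exposed as `loglik_path_` and asserted monotone in the tests.
* Convergence when the largest coefficient update is below 1e-8, cap of
  100 iterations.
* Standard errors from the inverse observed information (equal to the
  expected information for the logistic link).
* Quasi-complete separation is detected as any |β| exceeding 25 and flags
  the fit non-converged with a warning instead of returning silent output;
  rank deficiency is detected up front by pivoted QR and the error names
  the collinear columns.
* The physical-activity score is standardised to mean 0 / SD 1 within the
  analysis sample. Its original scale is survey-specific; standardisation
  makes the confounder's coefficient scale-free and leaves all other odds
  ratios untouched.
* All other predictors enter on their native scales — binaries as 0/1,
  environmental measures as 0–100 percentages/percentiles — so adjusted
  ORs read "per percentage point", matching how the index weights are
  interpreted downstream.

Crude odds ratios use the 2×2 identity ad/bc with the Woolf/Wald CI
`exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; no continuity correction is
applied, and a zero cell is a hard error naming the cell. The 1.96
multiplier is fixed (95% level). Group comparisons between cases and
controls use Welch's t-test, with binary indicators treated as 0/1 numeric
(i.e. proportions compared via means); correlation matrices are Pearson on
complete rows. No multiple-testing correction is applied anywhere: the
analysis reports per-variable 95% intervals as-is.

Tables printed as group percentages can be turned back into 2×2 counts with
`reconstruct_table`, which uses round-half-to-even; this matters because
e.g. 19.8% of 364 is 72.07 and the rounding convention is the difference
between reproducing printed CIs at two decimals or not.

## Buffer features

A cell belongs to a subject's buffer iff its centre lies within `radius_m`
(default 400 m) of the address; this centre-within-radius rule is the
simplest unbiased discretisation. Measures:

* `pct_residential`, `pct_vegetation`: 100 × (matching cells)/(valid cells
  in buffer). Residential means land-use class ∈ {private residential,
  public residential, rural settlement}.
* `avg_build_height_m`, `std_build_height_m`: mean and population SD of
  height over *built* cells (height > 0) by default. Including unbuilt
  ground as zeros would make the "average building height" of a half-built
  district approach half the true building height, which is not what the
  measure means; a `built_cells_only=False` switch implements the
  alternative reading. Buffers containing no built cell report 0/0 with a
  `no_buildings` flag.
* Buffers are clipped at the raster edge: the denominator counts only valid
  in-extent cells, and a subject whose buffer is more than half outside the
  extent is flagged `edge_clipped`.

The study protocol resamples all layers to a 1-m working grid before
extraction; `resample_raster` does this by nearest neighbour (value- and
class-preserving). On piecewise-constant layers the features are invariant
to the refinement within 1%, which the tests verify; the synthetic pipeline
therefore extracts at the native 10-m grid, where the same result costs two
orders of magnitude less.

Percentile normalisation of the two height measures uses the Hazen plotting
position, 100·(rank − 0.5)/n with average ranks for ties: order-preserving,
invariant under strictly monotone transforms, constant vectors map to 50.
Subject-level normalisation is computed over the analytic cohort by
default; the mapping stage normalises citywide instead, because the map
covers areas without subjects (`PercentileNormalizer` carries the reference
sample so both conventions are explicit).

Two extraction paths exist and are cross-checked against each other and
against a brute-force cell-enumeration oracle: an exact per-point extractor
and an FFT disk-convolution moving-window path that evaluates the same four
measures at every cell centre. The moving-window path is what the mapping
stage needs anyway; it also serves as a fast cohort-extraction
approximation (subjects snapped to their cell centre, at most half a cell
off) and is used for the large Monte-Carlo experiments.

## Index construction and mapping

From the Model-3 adjusted ORs, variables whose 95% CI excludes 1 are
retained and weighted by their percentage risk increase: `w = OR − 1`, and
`w = (OR − 1)/100` for a binary variable that enters the map as an
area-level population percentage (low education, rasterized zone-constant
from the planning-unit census attribute). Weights are derived from the
2-dp-rounded ORs by default — this reproduces the published formula
weights 0.006/0.01/−0.02/0.03 exactly — with an unrounded mode for
synthetic experiments where the extra precision matters.

The index surface is the cellwise weighted sum at the mapping resolution
(default the layers' native 10 m). The mapping-stage environmental layers
are the 400-m moving-window summaries — the same buffer operator applied to
subjects, reused for consistency since the original mapping neighbourhood
is not specified — with the height layers percentile-normalised citywide.
Cells whose window contains no building are nodata, and nodata in any input
propagates, so unsettled areas stay blank. Aggregation to planning units
takes the zone mean over valid cells and bins it to the nearest 0.1 (the
map's scale unit); zones with no valid cell are flagged instead of
numbered. Only variables with an available area-level layer can be mapped
(low education plus the four environmental measures); a significant
social variable without a census layer is reported in the regression but
cannot enter the map.

## Validation

Validation follows the four-step design: extract the mapped index at each
subject's location (half-open cell convention; nodata subjects excluded and
counted), refit the outcome on the index alone with the same IRLS engine,
and report the OR per 0.1-point index increase with its Wald CI. The
rescaling is applied to the coefficient (`exp(0.1·β)`), which is
algebraically identical to pre-dividing the index and is tested as such to
1e-10.

## Synthetic city and cohort

The generator emulates the study conditions, not any real geography:

* **City** (default 4 km × 4 km at 10 m): random rectangular residential
  estates (~30% cover), vegetation patches (~25%), commercial/industrial
  fabric, and building clusters inside developed patches. Each cluster
  draws a height regime (log-normal around 26 m, σ = 0.75 on the log scale)
  and a within-cluster spread (log-σ uniform on 0.40–0.90); individual
  buildings scatter log-normally around the regime. The shared local regime
  drives both the buffer mean and SD of height, which reproduces the strong
  positive correlation between the two (≈0.8 at 400 m, matching the ~0.82
  observed in the original high-density setting where historical low-rise
  districts and redeveloped towers mix). Rural settlements get low-rise
  (~7 m), low-variance clusters.
* **Planning units**: `n_tpu` rectangular tiles (default 25) with a
  Beta-distributed low-education census attribute (mean 65.5%, SD ~12
  points between zones).
* **Cohort** (default 4000 subjects): uniform placement on residential
  cells. Social covariates are drawn through a Gaussian copula with
  marginal rates defaulting to the control-group rates (older 9.5%, male
  50.5%, not married 28.1%, low education 65.5%, living alone 12.9%); the
  not-married/living-alone latent correlation is solved numerically so
  their Pearson phi hits the observed 0.55, and the remaining latent
  correlations are set to qualitatively matching moderate values. A
  subject's low-education probability is shifted by their zone's census
  attribute (centred so the study-wide marginal is preserved), giving the
  spatial clustering the mapping stage relies on.
* **Confounders** are generator assumptions, since their coding in the
  source survey is not public: independent Bernoulli indicators (dementia
  5%, cardiovascular 20%, respiratory 10%, alcohol 15%, smoking 10%) and a
  Gamma(4, 25) activity score (PASE-like, mean 100).
* **Outcomes**: the case probability is the inverse-logit of the Model-3
  linear predictor at configurable true coefficients (defaults sized like
  the published adjusted ORs; confounder effects are assumptions). The
  intercept is re-calibrated by root-finding so the expected prevalence
  matches the target 364/3930 ≈ 9.26%. GDS-15 scores are drawn uniform
  8–15 for cases and 0–7 for controls — only the dichotomy matters
  downstream. An optional missingness injector blanks one field in 0.35%
  of rows, matching the complete-case rate of the source analysis
  (3930/3944 retained).
* Every stage draws from its own seeded stream, so a configuration and
  seed reproduce rasters, cohort and outcomes bit-identically.

What the generator does **not** emulate: coastline/topography and the
resulting urban-rural separation, address-geocoding error, spatially
correlated confounding (confounders are independent of location), distance
decay in social covariates beyond the zone effect on education, and any
particular vegetation-residential correlation structure. Passing tests on
this city therefore demonstrate the correctness and calibration of the
estimators and of the pipeline plumbing — not that the published effect
sizes would be recovered from the real, undeposited data.

## Problem sizes in tests and experiments

The Monte-Carlo experiments run at sizes chosen to make their sampling
error small relative to the tolerance they are checked against: coefficient
CI coverage uses 50 synthetic cohorts of n = 3930 (the analytic sample
size) with cell-centred feature extraction; the null-calibration check uses
100 seeds of a smaller (1.5 km, n = 1500) city; type-I error of the Wald
test pools 500 replicates; validation-OR permutation calibration uses 100
permutations. The exact-vs-oracle buffer checks run on small rasters where
exhaustive enumeration is cheap.

## Known limitations

* Planar coordinates only; no CRS handling or geodesic buffers.
* Wald intervals throughout; no profile-likelihood or Firth correction, so
  small-sample or separated fits are flagged rather than rescued.
* The index inherits the ecological-inference caveat of the design:
  individual-level coefficients are applied to area-level layers.
* Rasters are exchanged as ESRI ASCII grids (text); heavyweight GeoTIFF
  I/O is intentionally out of scope.
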