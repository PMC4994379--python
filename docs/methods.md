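# Methods

This note documents the models implemented in `fireflux`, the choices made
where the underlying methodology left the design open, and what the
synthetic-scene tests do and do not demonstrate about real data.

## Grid model

All rasters share one local Cartesian grid: 0-based (row, col) indexing,
250 m pixels (6.25 ha, 0.0625 km²) and an affine origin. No projection or
sensor geometry (BRDF, clouds, compositing) is modelled; a real
georeferenced stack is a drop-in replacement provided all layers are
co-gridded. Rasters serialise as TIFF with the grid metadata in the
image-description tag; fire points as CSV/GeoJSON.

## Spectral unmixing

Per-pixel reflectance r (RED, NIR, SWIR) is modelled as r = E f + ε with E
the 3×3 endmember matrix (vegetation, soil, shade columns) and f constrained
to the 2-simplex (f ≥ 0, Σf = 1). The constraints are imposed — although a
plain least-squares inversion would be cheaper — because the shade fraction
is interpreted physically and thresholded downstream; unconstrained
fractions can leave [0,1] under noise and would break the floor rule. The
solver is exact, not iterative: the equality-constrained minimiser (a 4×4
KKT solve, vectorised over all pixels) is kept where feasible; otherwise
the optimum lies on a simplex edge, and the best of the three clipped
edge projections is taken. Unit tests verify agreement with an independent
SLSQP constrained solver on noisy pixels.

Default endmember spectra (reflectance): vegetation (0.04, 0.45, 0.20),
bright dry soil (0.25, 0.35, 0.42), shade/burn (0.02, 0.03, 0.02). These
are nominal values for the three scene components; with real imagery they
should be picked from pure pixels of the scene.

## Segmentation and burn classification

The shade image is rescaled to digital numbers (DN = round(255·shade), a
fixed scale, not min–max, so thresholds are scene-independent) and
segmented by 4-connected region growing: a pixel joins a region while its
DN differs from the running region mean by at most 8. Regions under
4 pixels are merged into the adjacent region with the closest mean shade;
merging is done sweep-wise with all small regions resolved simultaneously
(pointer jumping, cycles collapsed to the smallest id), which keeps the
pass count logarithmic on noisy, fragmented images.

Region means are then split by an iterative two-centroid procedure (1-D
two-means initialised at the extremes). Regions in the high-shade cluster
whose own mean exceeds a burn-shade floor (default 0.5) are labelled
burned. The floor replaces two manual elements of the original workflow —
the unsupervised classifier's internal thresholds and the human
post-classification editing — with an automatic, reproducible rule; it
prevents labelling the darker half of a fire-free scene as burned. The
25 ha minimum mapping unit (4-pixel components) is the second automatic
cleanup.

Per-date masks accumulate in date order: a pixel's first-burn month is the
earliest detection, later detections are ignored, so the map is cumulative
and carries no information on repeated burns of the same pixel.

## Biomass-loss model

The retention law B_after = α·B_initial is fitted through the origin with
the York errors-in-variables estimator. The through-origin iteration

    W_i = 1/(sd_y² + b² sd_x²),  β_i = W_i(x_i sd_y² + b y_i sd_x²),
    b ← Σ W_i β_i y_i / Σ W_i β_i x_i

has as fixed point the exact stationary point of the chi-square
Σ W_i(b)(y_i − b x_i)² (β_i is the error-weighted projection abscissa of
each point onto the line); the slope variance is 1/Σ W_i β_i². Convergence
is declared when the slope moves < 1e-10 between iterations, with a cap of
500 iterations; these are fixed numerical constants. The intercept variant
implements the standard centred form. Limits are verified numerically:
negligible x-errors recover weighted least squares, dominant x-errors
recover the inverse-regression slope Σy²/Σxy, and a 1-D grid search of the
chi-square agrees to 1e-4 on small instances.

The loss applies only where the burn flag is set; the model represents
short-term (first-year) loss only — delayed mortality beyond one year is
out of scope.

## Emission bookkeeping

Unit chain per class: burned pixels × 6.25 ha × mean loss (Mg ha⁻¹) gives
Mg dry biomass; × 0.48 gives Mg C; ÷ 1e6 gives Tg C. Pathway split of a
class total T:

* COMBUST: gross = T, committed = 0;
* DEFOR_SPLIT: gross = committed = T/2 (the in-year gross counts only the
  combusted half; no first-year decay of the dead half — the published
  per-class figures show gross exactly half of total for these classes);
* DECAY: gross = T·(1 − e^(−k)), k = 0.17 yr⁻¹, committed the remainder.
  The exponential first-year release (1 − e^(−k) = 0.1563), rather than k
  itself, is used because the published gross/total ratios of all three
  decay classes equal 0.1563.

Percentages are computed on unrounded values and rounded at report time
(class burned percentages to 2 decimals). The national-target ratio divides
total carbon loss (Pg) by the 0.11 Pg C yr⁻¹ annualised reduction target.
Aboveground biomass only; litterfall, coarse woody debris and soil
combustion are excluded.

## Monte Carlo uncertainty

Defaults: 100 repetitions (tests use 1000 where variance calibration is
asserted), slope sd 0.034, land-cover accuracy 0.80 (its published
confidence interval 0.74–0.87 is exposed as a config option but not varied
by default, since the original analysis states only the point accuracy),
burn accuracies 0.992 (forest) and 0.9693 (non-forest). Continuous inputs
get Gaussian draws; per-pixel biomass is treated as an independent normal
with the error map as 1σ, truncated at 0. Categorical rules: a pixel keeps
its class with probability equal to the accuracy, otherwise it is
reassigned frequency-weighted among the other classes (the confusion
structure is unpublished; this preserves the marginal class distribution);
burn flags are cleared with probability 1 − accuracy and never created
(inventing commission locations would require an unstated spatial model).

Two known properties: (i) zero-truncation makes total carbon a *convex*
function of biomass for low-biomass classes (mean ≲ sd), so the MC mean
sits slightly above the deterministic value there — the linearity check in
the tests therefore runs on a forest-only scene where truncation is
negligible; (ii) slope draws are clamped into (0, 1) since retention
outside that range is unphysical (at sd 0.034 around 0.7084 the clamp is
never active in practice).

## Regional scaling

Sampling units for the fire-count → burned-area regression are burned
connected components whose majority class is forest; this matches a
polygon-level relation between scar area (ha) and detection count. The
weighted fit uses an OLS pre-fit, samples split into 5 equal-size groups by
fitted value (the grouping count is this package's choice — it balances
group size against variance resolution at the sample sizes used), group
weight = 1/(group residual variance), and a weighted refit via statsmodels
WLS. Prediction intervals use the weight of the group whose fitted-value
range contains the new count. An exactly collinear input degenerates to
uniform weights with an `exact_fit` flag; a mixture of zero- and
nonzero-variance groups raises instead, signalling degenerate grouping.
Extrapolated areas are floored at 0. Scaled emissions follow the forest
DECAY pathway, with bounds from the slope's fitted range (0.6744–0.7424);
a smaller retention slope means more loss, hence the bound ordering.

## Synthetic-landscape generator

The generator's defaults are the study conditions: the 15-class legend
with its published area shares, per-class burned fractions and biomass
means/1σ errors, the published monthly burned-area shares as burn-month
weights (September ≈ 0.68), and 250 m pixels.

* **Land cover** — quota-capped multi-source region growing from seeds on
  a jittered grid (blue-noise spacing), mean polygon ~160 px (10 km²).
  Classes stop claiming pixels at their area quota, so realised shares
  track requests to well under 2 percentage points on grids ≥ 200×200
  while staying spatially coherent (downstream segmentation needs patches,
  not i.i.d. speckle).
* **Biomass** — per-class truncated normal (the published data give only
  means ± errors; this is the simplest law matching them); the error
  raster stores the 1σ used. No within-class spatial autocorrelation is
  modelled — none is published — so biomass texture is a stand-in.
* **Burns** — connected patches grown inside their class with lognormal
  sizes (log-mean 3.5, log-sd 1.2 px: a heavy-tailed mix dominated by
  > 5 km² patches, the minimal choice matching the observed size
  structure), minimum 4 px, per-class burned fraction targeted within
  ±20 % relative. Unburned islands smaller than 4 px inside patches are
  filled: the map cannot represent sub-mapping-unit features, so the truth
  must not contain them either.
* **Reflectance** — truth fractions per class (shade ≤ 0.2 unburned),
  burned pixels switch to (0.05, 0.05, 0.90); reflectance = fraction-
  weighted endmember sum + Gaussian noise (default sd 0.01, a nominal
  surface-reflectance noise level).
* **Fires** — per-patch Poisson counts with mean proportional to patch
  area (expected total = rate × patch count), uniform placement within the
  patch, confidence uniform over a configurable range, plus a small
  false-detection fraction outside scars.
* **Plot pairs** — latent biomass uniform on 20–350 Mg ha⁻¹ with Gaussian
  errors on both axes (default 15 Mg ha⁻¹ each).

What passing tests show: the mapping chain is exact at zero noise and
F1 ≈ 1 at reflectance noise sd 0.02 *on piecewise-constant scenes with a
0.6–0.8 shade contrast between burned and unburned*. Real imagery has
within-class texture, mixed boundary pixels, clouds and smoke, so real-data
accuracy must be established by an independent validation, not inferred
from these tests.

## Problem sizes and determinism

Test and acceptance runs use 400×400 grids for the mapping round trip,
200×200 for Monte Carlo calibration (1000 repetitions), 500 plot pairs for
slope recovery and 100 replicates of 200 samples for the WLS coverage
check — sizes at which every asserted statistic is stable. All randomness
derives from explicit seeds via `numpy` `SeedSequence` streams keyed by
(seed, stage); a pipeline run is byte-reproducible from its global seed.

## Known limitations

* No repeated-burn accounting (cumulative map only), no sub-25 ha fires.
* The burn-shade floor and the two-centroid labelling are proxies for an
  unpublished unsupervised classifier plus manual editing.
* The regression grouping rule (5 groups) and the polygon sampling unit
  are this package's choices; the original coefficients are unpublished,
  so regional extrapolation is validated structurally (recovery and
  coverage on synthetic data), not against published coefficients.
* Biomass errors are treated as independent per pixel; spatially
  correlated error would widen class-level uncertainties.
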