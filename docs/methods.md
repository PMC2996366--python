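# Methods

## Scope and model

The package implements the saturation-sampling land-use-regression
workflow for NO2 around a small airport. Concentrations are modeled as
an ordinary least squares GLM: session fixed effects (the last session
label is the reference and is absorbed into the intercept) plus linear
terms in GIS covariates, with homoscedastic Gaussian errors and
classical inference. No spatial error structure is modeled: passive
samplers integrate over one- to two-week deployments, and the
covariates themselves carry the spatial structure the design can
resolve.

All geometry is planar, in meters, x = easting / y = northing, with
azimuths in compass convention (degrees clockwise from north). Inputs
are assumed to be projected upstream; readers reject coordinates that
look like geographic longitude/latitude.

## GIS covariates

- **Distances** are exact point-to-polyline Euclidean distances.
- **Buffer road lengths** clip each polyline edge against the buffer
  circle analytically (quadratic in the segment parameter); the
  discretized brute-force computation survives only as an independent
  test oracle. Lengths are computed per road class and in total at
  each configured radius (default 100/200/300/400 m; radii above 400 m
  are deliberately not constructed — NO2 gradients near roads decay
  within a few hundred meters and wider buffers converge across sites).
- **Sector lengths** partition the buffer into eight 45° wedges
  centered on the compass directions. A point exactly on a wedge
  boundary belongs to the clockwise sector; a segment passing exactly
  through the buffer center is split there. The wedge lengths sum to
  the total clipped length by construction, and this conservation is
  asserted in tests.
- **Wind-weighted lengths** multiply each sector length by the
  fraction of time wind blows *from* that direction (upwind
  convention: road mass upwind of the sampler is what transport
  carries across it) and sum. Computed at the 200 m radius only. They
  are always present in the covariate table but excluded from the
  model-building candidate pool by default (`include_wind_weighted`),
  since period-averaged wind weighting adds no explanatory power at
  these temporal scales; when enabled they share an exclusion group
  with the unweighted length of the same class.
- **Kernel traffic density** discretizes the network at 1 m steps and
  sums ADT × step × K(d) with the quartic kernel
  K(d) = 3/(πr²)(1 − d²/r²)² (a uniform kernel is available for
  sensitivity; it needs a finer step near the search radius because it
  is discontinuous there, which the quartic is not). The SI result
  (vehicle·m/day per m²) is multiplied by a configurable output scale
  (`density_scale`, default 0.3) chosen once so that the default
  campaign's 100 m density has a mean in the tens, the magnitude scale
  on which published density coefficients of this kind are expressed.
- **ADT-weighted road length** (vehicle·m/day) is the scale-free
  companion: Σ ADT × clipped length, at 100 and 200 m.

## Measurement QA

Laboratory blanks estimate the assay zero; their mean is subtracted
from every measured concentration, negatives are clamped to zero and
counted, and blanks leave the analysis set. Field blanks are reported
but not subtracted (only the laboratory-blank correction is part of
the analysis contract). Duplicate precision uses the two-observation
standard deviation |a − b|/√2 per pair, averaged across pairs and
divided by the overall mean concentration (in percent). QA operates in
whatever single unit the records carry; no ppb/µg·m⁻³ conversion is
attempted because it would require deployment temperature and
pressure. Duplicate tubes stay in the bundle for QA but are excluded
from the regression table — they are co-located repeat measurements,
not independent observations.

## Synthetic campaigns

The generator emulates the statistical structure of a three-session
saturation campaign around a small airport on a 5 × 5 km domain:

- **Road network**: one class-1 limited-access highway near the east
  edge (ADT 150,000), an airport connector (100,000), a north
  connector (80,000) and a terminal access road along the east fence
  (60,000) as class 2, four class-3 arterials (ADT 20,000–35,000)
  framing the airport and following the commercial corridors, and a
  dense 250 m class-4 street grid (ADT 300–1,500) clipped out of the
  airport block. Arterials cluster near the traffic corridors so that
  arterial proximity co-varies with the traffic field, as it does in
  commercially zoned study areas.
- **Airport block**: terminal point, two crossing runways named 5/23
  and 16/34, centroid, and a rectangular fence polyline.
- **Sampling design**: fence samplers evenly spaced by arc length
  along the fence; community samplers drawn mostly from a ring 0.5–2.6
  km around the airport, partly domain-wide, with a deliberate share
  near major roads (the highway oversampled so that ~5% of records
  fall within 100 m of class 1 — its footprint is otherwise too sparse
  to estimate). Session shares are 0.26/0.385/0.355, the first session
  thinner. `n_fence`/`n_community` are retention targets: the
  generator deploys n/(1 − loss) samplers and drops each with the
  field-loss probability 51/695 ≈ 7.3%, so the default request
  (253 + 391) retains ≈ 644 records in expectation.
- **Concentrations**: NO2 = 12.64 + {+2.18, +1.89, 0} per session
  − 0.00140·dist_terminal + 0.00830·density₁₀₀ + 0.0230·len_class1₁₀₀
  + 0.00381·len_class2₂₀₀ − 0.00286·dist_class3 + N(0, σ²). The noise
  σ is calibrated in closed form per campaign so the generative
  R² = var(signal)/(var(signal) + σ²) equals 0.32 (typically
  σ ≈ 3.4 ppb); fitted R² then lands in the low 0.3s. Negative draws
  are possible in the far noise tail and are left for QA to clamp.
- **QA features** (independently seeded, individually switchable):
  duplicate tubes on 11% of samples with pair noise σ = 3.0 ppb (sized
  so expected relative precision is ≈ 14.5% at an 11.6 ppb mean), ten
  laboratory blanks (mean 0.01) and twenty-two field blanks (mean
  0.09) per session.
- **Wind roses**: W-dominant with a SW tilt in the fall session and NW
  tilts in spring/summer.

What the generator does **not** emulate: dispersion physics (plumes,
landing/take-off cycles), temporally resolved emissions, spatially
correlated residuals (noise is i.i.d.; an autocorrelated-noise hook
would slot into `simulate_no2`), measurement-error heteroscedasticity,
and real road-network topology. Passing tests therefore demonstrate
that the pipeline recovers a linear spatial signal of realistic
magnitude under realistic sampling geometry — not that any particular
field dataset satisfies the linear model.

## Model building

Screening fits one session-adjusted bivariate GLM per covariate;
zero-variance and undefined covariates are skipped and logged.
"Strongest association" means smallest p, ties broken by larger |t|,
then lexicographic name. Structured stepwise then:

1. always includes the session dummies (never dropped);
2. enters the single best significant airport proxy;
3. builds a candidate pool from the traffic-proxy and distance-to-road
   categories — the best significant variant per *base metric* (the
   underlying data source: each class's length family, total length,
   the ADT-weighted density/length family, each class's distance),
   restricted to buffer radii ≤ 200 m (`candidate_max_radius_m`) —
   and tries candidates in ascending screening p;
4. keeps a candidate only if its multivariate p < `p_enter` (0.05) and
   no term with the same base metric is already present; after each
   entry, any term whose p rose above the threshold is evicted, so the
   final model never contains a non-significant covariate.

Retention is by p-value alone (not adjusted-R² improvement). The
automated comparator is classical forward stepwise with backward
elimination at the same threshold over all screening-significant
variants, with no category, radius or base-metric constraints; its
report flags coefficient signs that flip relative to the screen and
covariate pairs with |ρ| ≥ 0.95 — the constrained and unconstrained
routes typically coincide on low-collinearity data and diverge exactly
where collinearity makes unconstrained selection uninterpretable.

Partial R² is sequential: the increment in R² when a term group enters
(sessions first, then covariates in entry order). The increments
telescope to the total R² exactly, which is asserted to 1e-10.
Interaction checks refit the final model with session × term columns
and test the interaction block with an F-test, reporting per-session
slopes.

## Attribution

The prediction grid is axis-aligned with inclusive edges over the
bounding box of the sampling records (the "domain" for the farthest
point is the sampled extent, configurable via the grid input). Grid
covariates use the same radii and kernels as sampling covariates; the
session-average surface is the unweighted mean of per-session
predictions (sessions had different lengths, but no weighting is
defensible without them). Points inside the fence are computed and
flagged rather than masked. The terminal contribution at a grid point
is β_terminal × (d − d_max), zero by construction at the farthest grid
point and positive elsewhere when β_terminal < 0 (a warning is issued
otherwise); percentages are relative to the session-average
prediction, with non-positive predictions excluded from the percentage
summaries.

## Sensitivity analyses

Subsampling is simple random sampling without replacement, stratified
by session so the session dummies stay estimable; all runs are
reproducible from (seed, config), and the full fraction reproduces the
reference fit replicate-for-replicate. The fence/community split
refits the fixed final term set per stratum and reports percent
differences against the full fit; in the synthetic design the
fence-only stratum loses power because fence samplers deliberately sit
at near-uniform exposures (that is what fence saturation is for) and
the terminal access road runs beside the east fence, making
within-fence covariates collinear. Per-session models rerun the full
structured selection inside each session without dummies and report
agreement in the selected source categories (airport vs traffic)
across sessions. The default replicate count is 200 (configurable);
the published-style "10–50% variation across half-data samples" is
treated as a qualitative expectation, not a test bound.

## Numerical conventions and edge cases

- Disc clipping solves the circle–segment quadratic directly; tangent
  and non-intersecting cases fall out of the discriminant sign.
- Sector ties (a point exactly on a boundary azimuth) go to the
  clockwise sector — measure zero, fixed for determinism.
- Rank-deficient designs raise an error naming the dependent columns
  (pivoted QR); stepwise treats such candidates as unenterable.
- GeoJSON emitted by the generator rounds coordinates to millimeters
  so byte-identical output is reproducible across runs of a seed.
- CSV output keeps full float precision (shortest round-trip repr);
  read-after-write reproduces values to 1e-12 relative.
- Problem sizes used by the test suite: one default campaign
  (~634 analysis records) shared session-wide; 100 noise replicates
  for recovery/selection checks; 1000 single-covariate screens for the
  type-I error check; 200 subsample replicates for stability. These
  sizes make the full suite run in well under a minute of compute for
  the heavy statistical tests while keeping Monte Carlo error small
  relative to the asserted bounds.
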