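# Methods

This note documents the models and procedures implemented in `gpgraze`, the
defaults they ship with, and what the synthetic experiments do and do not
demonstrate.

## Synthetic terrain and herds

**Terrain.** Each farm is a square paddock (default 34.5 ha, the typical
hill-country paddock size this kind of study works with) on a regular
elevation grid with 16 m cells — the resolution of the national digital
elevation models used to annotate collar data.  Elevation is a Gaussian-
smoothed white-noise field rescaled to a configurable relief (default 300 m
over the paddock, within the 200–1000 m elevation band typical of the
terrain being emulated).  Slope and aspect derive from the elevation grid by
Horn's 3×3 finite-difference method, the convention of common GIS surface
toolboxes; edge cells use clamped neighbourhoods.  A plane rising 1 m per
metre east therefore has 45° slope at every interior cell, which the tests
pin.

**Movement model.** Cows follow a correlated random walk at the fix interval
(default 5 min): the new heading is the previous heading plus a drift term
and wrapped-normal turning noise whose concentration κ sets path tortuosity
(sd of a turn = 1/√κ radians; κ→∞ walks straight, κ=0 is uniform).  The
drift pulls along the local upslope gradient with weight `uphill_bias` and
toward a preferred relative elevation with weight `elevation_attraction`
(saturating within 10% of the relief, so cows settle into an elevation band
rather than oscillating).  Step lengths are lognormal with unit-mean
parametrization, so the marginal mean step equals the profile's
`step_length_mean`.  A per-day lognormal multiplier (log-sd
`day_variability`) scales step lengths and uphill drift, creating genuine
between-day variance — the CV-type behaviours differ between genotypes by
construction, not as a side effect of sampling noise.  Positions reflect at
the paddock fence (cows do not absorb at fences), isotropic Gaussian GPS
error (default sd 5 m) is added to the recorded positions, and fixes drop
out independently (default 10%, comfortably above the 75% fix-rate filter
so whole days are rarely lost).

**Genotype profiles.** The five stock profiles separate the genotypes on
several generative axes at moderate effect sizes (roughly 2–4 generative
SDs between extreme genotypes on step length, turning concentration,
elevation attraction and day-to-day variability).  Cows within a genotype
are not clones: each cow's parameters are jittered by a unit-mean lognormal
factor (default rel. sd 0.12), which is what makes the within-genotype
scatter realistic and the classification problem non-trivial.  A null
scenario (`identical_profiles`) gives all five genotype labels one shared
phenotype.

**Determinism.** All output is a pure function of (config, seed).  Per-cow
random streams are derived from `SeedSequence(seed, farm_index, cow_index)`,
so enlarging the herd never perturbs existing trajectories.

## Trajectory quality control

The cleaning chain mirrors standard collar-data practice: (1) annotate each
fix with elevation/slope/aspect sampled from the terrain grids (nearest cell
by default, bilinear optional); (2) iteratively remove position spikes —
fixes whose implied inbound *and* outbound speeds exceed 2.5 m/s (sustained
cattle walking speeds are well below this), or whose turn exceeds 170° at
speeds above 1.5 m/s (the out-and-back signature of a lone spike) — until
stable, which makes the filter idempotent; (3) split by calendar day (local
midnight, timezone offset configurable) and exclude handling days from a
supplied calendar; (4) exclude days with fewer than 75% of scheduled fixes
(inclusive boundary: exactly 216 of 288 is kept); (5) drop cows with fewer
than seven valid days; (6) flag hill days where the herd-median fix slope is
strictly greater than 8°.  The speed/turn thresholds are parameters, not
biology: the contract tests pin the filter's behaviour at its defaults.

## Behaviour metrics

Eighteen daily metrics per cow-day (documented in `gpgraze.metrics`), then
per cow the across-day mean of each and the across-day CV of all but the
farm-centred mean elevation: 35 variables.  Decisions worth recording:

- CVs use the sample (n−1) SD and are computed on untransformed daily
  values; the CV variable itself is then transformed per the shipped map.
- Quantiles (85th/15th of elevation and slope) use linear interpolation
  between order statistics — the default of the analysis environments this
  field uses — and the choice is pinned in tests.
- A day whose fixes are collinear or fewer than three has no convex-hull
  area; `hr_mcp` and `sp_tortuosity` are treated as missing for that day
  (not zero), avoiding infinite tortuosity.  Days missing one metric leave
  the other metrics' aggregation untouched.
- Herd-relative variables need at least two cows on the same farm-day;
  the anchors (+3500 m for adjusted distance, +350 m for adjusted
  elevation) keep those variables on the scale of the raw means.
- Farm-centred elevation variables subtract the farm's grand mean daily
  elevation over the cow-days *of the current analysis cohort*, and are
  recomputed whenever cohort membership changes (e.g. after balancing).
- The transformation map is shipped verbatim, but a transform whose domain
  a variable violates (log of a CV that is negative because its mean daily
  value is negative — a real occurrence for farm-centred CVs) is, under the
  pipeline's default policy, skipped and logged in the run provenance
  rather than silently coerced; strict-error and zero-offset policies are
  available.

## Cohort construction

Unbalanced genotype cohorts degrade classifiers, so the training set is
built by uniform random under-sampling: 4 cows per genotype × farm cell
(4 farms × 5 genotypes → 80 cows, 16 per genotype), after excluding
genotypes rarer than 5% and cows flagged by the outlier screen.  Remaining
eligible cows form the unbalanced testing set.

The outlier screen estimates robust location/scatter by the minimum-
covariance-determinant search and flags squared robust Mahalanobis
distances beyond a χ² quantile (the raw distances are first rescaled so
their median matches the χ² median, correcting small-sample scale
inflation).  Two deliberate choices: the assumed clean fraction is 0.9
(the screen targets individual anomalies; a lower support fraction lets a
20% genotype with a genuinely distinct phenotype be swallowed whole), and
the pipeline applies the screen *within* genotype after removing genotype ×
farm cell medians — in a design where genotype differences in location and
scale are the signal under study (the quadratic-discriminant setting), an
outlier must mean "unusual for its own genotype", not "member of an
unusual genotype".  The screening α defaults to 0.01.

Missing profile cells are completed by iterative low-rank EM-PCA: columns
are scaled, missing cells start at column means, and each sweep refits the
column means plus a rank-r principal-component reconstruction and refills
the missing cells; r is chosen by cross-validation on 10% of the observed
cells held out.  On exactly low-rank data the imputer recovers deleted
cells to numerical precision, which the tests verify.

## Discriminant modelling

Variables are centred and scaled with training-set parameters (testing data
always transformed with the *training* parameters).  Backward stepwise
selection starts from all 35 variables: each round fits the canonical LDA
(generalized eigenproblem of between- vs within-class scatter; axes scaled
to unit pooled within-class variance; min(G−1, d) axes — four for five
genotypes) and ranks variables by their pooled score, the sum of absolute
canonical coefficients across axes.  Candidates are tentatively dropped in
ascending score order; a drop is accepted iff the resubstitution accuracy
of the working linear classifier does not decrease (ties favour parsimony),
and the procedure converges when no variable can be removed.  Afterwards a
collinearity stage removes the highest-VIF variable until all VIFs are
below 10; a per-variable override list supports analyst-accepted
exceptions, which the trace records.  Pooled scores are computed on
standardized variables so they are comparable across units; score ties
break by variable name for determinism.

Box's M (with the standard χ² correction factor) tests covariance
homogeneity across genotypes; when it rejects at 0.05 the final classifier
is quadratic (class-specific covariances), otherwise linear (pooled).
Priors default to equal, matching the deliberately balanced training
design, and remain the training priors when predicting the unbalanced
testing set.  Ill-conditioned class covariances are shrunk toward their
diagonal with a warning.  Ties in the discriminants resolve to the lowest
class label.  Fitted models serialize to JSON (means, covariances, priors,
standardization, schema version) and reload to an identical predictor.

## Association statistics

- **MANOVA map**: canonical-variate analysis on the selected variables;
  per-axis share of discriminable variation = eigenvalue share; group
  centroid confidence ellipses use a χ² radius in canonical space (where
  the pooled within covariance is the identity) scaled by 1/√n_g, with the
  coverage Bonferroni-split across the G groups.  The per-variable p-values
  are univariate F tests within the same framework and are labelled as
  such.
- **Two-way ANOVA**: additive fixed effects (genotype or variant-presence +
  farm block), type-I sums of squares on balanced designs (orthogonal;
  order is immaterial) and type-II otherwise; the genotype × farm
  interaction is a diagnostic that is skipped when a cell is empty.
- **Variant tests**: each genotype decomposes into its allele variants
  (AB → {A, B}); per variant a presence indicator enters the two-way
  ANOVA; a variant without contrast is skipped with a note.
- **Levene**: Brown–Forsythe variant (median-centred) by default.
- **ICC2**: two-way random-effects intraclass correlation, single measure:
  ICC2 = (MS_R − MS_E)/(MS_R + (k−1)MS_E + k(MS_C − MS_E)/n) for n cows and
  k days.  Unbalanced panels reduce to the largest complete sub-panel by
  listwise day alignment; REML-type component estimation is out of scope.
- p-values are reported raw with annotations at the conventional 0.1/0.05
  thresholds; no multiple-testing correction is applied, and the report
  says so.

## Problem sizes and calibration checks

The default synthetic experiment uses 4 farms × 5 genotypes × 7 cows × 15
days of 5-minute fixes (≈540k fixes); 4 cows per cell are sampled into the
80-cow training set and the remainder (≈45 after screening) form the
testing set.  The acceptance suite verifies, at these sizes: type-I rates
of Box's M, Levene and Shapiro–Wilk within [0.03, 0.07] at α = 0.05 over
500 replicates; QDA at chance (20%) for identical class distributions; ICC2
calibration under stated variance components (±0.05 at n = 40, k = 15); and
full-pipeline genotype recovery (training accuracy ≥ 3× chance, testing
accuracy above chance by ≥ 3 binomial SEs) across 10 seeds, collapsing to
chance with unstable variable selection when all genotype profiles are
identical.

## What the synthetic experiments do not show

The generator reproduces the *measured* phenotype axes (distances,
tortuosity, elevation use, and their day-to-day variability), not cattle
behaviour: there is no grazing/resting state switching, no social
interaction, no water-point attraction, no diurnal rhythm, and GPS error is
isotropic Gaussian without terrain-dependent multipath.  Genotype effects
are injected directly into movement parameters, so a passing recovery test
demonstrates that the pipeline detects such effects when they exist at the
configured sizes — it says nothing about whether real genotypes have
effects of that size.  Generative defaults are fixtures chosen once for
realism, not estimates fitted to any herd.  Coordinates are planar metres
throughout; no geodesy or CRS re-projection is performed.
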