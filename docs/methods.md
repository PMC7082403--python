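# Methods

## The problem

In perennial tree crops such as almond, the ceiling on yield at a given
canopy size is set by how much photosynthetically active radiation (PAR) the
canopy intercepts, while the *realised* yield falls below that ceiling by an
amount driven by tree age, weather stress and management.  This package
implements that two-part decomposition as a reusable pipeline:

1. a **boundary-line (frontier) analysis** that estimates the light-limited
   yield potential from the upper envelope of the yield vs. light
   interception cloud, and
2. a **yield-gap analysis** that models the normalized yield
   `y_n = y_o / y_p` (observed over potential) with interpretable machine
   learning — random-forest importance, partial dependence, and
   representative CART rules — against engineered climate features.

Because the multi-orchard field campaigns this kind of analysis runs on are
rarely public, the package ships a synthetic-data generator that emulates
their structure with known ground truth, so every stage is testable and the
pipeline's ability to *recover* planted effects is itself under test.

## Light interception

Per-tree fractional PAR interception is `fPAR = 1 − PAR_below / PAR_above`,
averaged over the sampled trees to give plot-level light interception (LI,
stored as a fraction in [0, 1]; displayed in percent).  Below-canopy readings
up to 5% above the reference are clipped to fPAR = 0 as sensor noise; larger
excursions are rejected as measurement inconsistencies.  No within-plot
outlier filtering is applied before averaging.

## Frontier estimation

Plot-years are binned by LI percent into half-open 5%-wide bins
(`[k·5, (k+1)·5)`; a value exactly on a boundary joins the upper bin).  In
each bin with at least `min_bin_count = 20` members, the top
`ceil(0.1·n)` records by yield form the upper decile; ties at the cutoff are
resolved by stable record order.  The decile's mean LI and mean yield give
one point per bin, and the potential line is the zero-intercept least-squares
fit over those points, `slope = Σxy / Σx²` (x in LI percent).  The fit
quality reported (`r2_binmeans`) is computed on the bin means, not the raw
cloud.  `min_bin_count = 20` guarantees the decile holds at least two
samples; sparse extreme bins are excluded, not imputed.  Bin means are
equally weighted — no weighting by bin population — and a per-cultivar
frontier is available via a cultivar filter.

The gap statistic is the exact quotient `y_n = y_o / y_p`; values above 1
(plots beating the fitted frontier) are preserved, not clipped.

## Climate features

Monthly gridded climate (precipitation, Tmax/Tmin/Tmean, maximum vapour
pressure deficit) and daily weather (Tmax, shortwave radiation SRAD,
daylight hours) are turned into plot-year features:

* monthly and seasonal means at two lags (current and previous calendar
  year), with meteorological seasons and the winter of year Y defined as
  Dec(Y−1)/Jan(Y)/Feb(Y);
* monthly extreme-hot-day counts (`HotDays`): a day is hot when its Tmax
  strictly exceeds that calendar month's 90th percentile
  (linear-interpolation quantile) of daily Tmax pooled over the reference
  decade, computed per cell (configurable to pooled);
* long-term seasonal and annual climatology per cell (`ltm_*` columns).

Orchards are joined to climate cells by nearest coordinates (ties to the
lowest cell id).  Rows lacking any feature — in particular the first study
year, which has no previous-year lag — are dropped with a logged count
rather than imputed.

## Feature screening

Candidate climate features are ranked by |Pearson r| with the target;
walking down that ranking, a feature is kept if |r| > 0.15 and its absolute
correlation with every already-kept feature *of the same category* is below
0.50.  Categories follow the variable groupings {precipitation, temperature,
VPD, radiation/daylength, extremes}; absolute values are used throughout so
negatively correlated stressors pass.  Two design choices deserve note:

* **Long-term climatology columns form their own categories.**  They carry
  between-site (spatial) variation while the lagged columns carry
  interannual anomalies; treating them as interchangeable lets a static site
  proxy displace a year-specific stressor on a correlation coin-flip, which
  defeats the screen's purpose.
* **The gap model always retains the two canonical seasonal stressors**
  (current-year summer VPDmax and winter Tmean) alongside the screen's
  selections.  Hypothesis-driven retention keeps the stress response
  curves of primary scientific interest estimable even when the redundancy
  rule would swap one out for a highly correlated proxy (e.g. a single
  summer month).  Scenario C uses the screen's output unmodified.

## Models and interpretation

The workhorse is a random-forest regressor (bootstrap resampling, p/3
features per split, minimum leaf 5, 500 trees by default — the classic
regression-forest configuration; all exposed in config).  Cultivar codes are
one-hot encoded for model fitting; for the Pearson screen the integer code
is used directly, with the caveat that this ordinal encoding is arbitrary.

* **%IncMSE importance**: for each feature, its column is permuted and the
  forest's *out-of-bag* MSE recomputed;
  `%IncMSE = 100 · (MSE_oob_permuted − MSE_oob) / MSE_oob`, averaged over
  `n_repeats = 10` permutations.  Out-of-bag permutation is the classic
  forest importance; it is implemented here directly (per-tree OOB index
  recovery) because the scikit-learn permutation importance is
  validation-set based, not OOB.
* **Partial dependence**: brute-force marginalisation — for each of 50 grid
  values equally spaced between the feature's 1st and 99th percentiles
  (tails excluded against extrapolation artifacts), every row's feature is
  set to the value and the forest's predictions averaged.
* **Representative tree**: `n_candidates` CART trees (depth ≤ 3) are fitted
  on bootstrap resamples and scored by RMSE on their own out-of-bag rows;
  the best tree's split structure is reported as explicit threshold rules.
* **Scenario comparison**: sixfold cross-validation (seed-shuffled
  row-level folds) of four predictor sets — A biological incl. measured LI;
  B adding the full climate set; C adding only the screened climate set;
  D the full set minus LI.  Metrics are RMSE, R² and RPIQ
  (IQR of the held-out observations / RMSE); means ± standard deviations
  (labelled as sd) across folds are reported.  Fold assignment is random at
  the plot-year level by default, with orchard-grouped folding available.

The yield-gap target is the normalized yield `y_n` itself; "gap" in prose
refers to its shortfall from 1 (the two are monotone images of each other).

## Synthetic study conditions

The generator emulates a 33-orchard, 10-year campaign (24 plots per
orchard-year; ~7,900 plot-year records) on a 35.0–39.5 °N latitude gradient
with one climate cell per orchard:

* **Climate**: sinusoidal seasonal cycles shifted by latitude (southern
  cells warmer, higher summer VPDmax, slightly sunnier), plus per-season
  interannual anomalies (sd 1.3 °C, 3.0 hPa, 20 W m⁻²), monthly noise, and
  daily noise around the monthly values.  Interannual swings of this size
  match the year-to-year variability of Central Valley winters and summers
  and make current-year stressors statistically distinguishable from their
  long-term spatial proxies.  `tmin ≤ tmean ≤ tmax` holds by construction.
* **Light interception**: saturating in age,
  `LI = 0.80·(1 − e^(−0.35·age))` (plateau ≈ age 7), a small long-term
  radiation perturbation, Gaussian noise (sd 0.03), clipped to [0.05, 0.90].
  Ages are drawn uniformly on 1–22 per plot-year.
* **Potential**: linear through the origin, 57.9 lbs/acre per LI point.
* **Gap**: multiplicative,
  `g = 0.90 · g_age · g_winter · g_vpd · g_srad · e^ε`, capped at 1.05,
  with `ε ~ N(0, 0.10)`.  A multiplicative lognormal error keeps yields
  non-negative with spread growing in the mean.  The stress terms are
  threshold-shaped: a concave young-orchard ramp ending at age 5
  (`1 − 0.15·√((5−age)/5)`; the concavity concentrates the transition at
  the maturity age so the planted 5-yr rule is identifiable by a CART
  split, rather than splitting mid-ramp), a warm-winter penalty of
  0.08/°C above 10 °C winter Tmean, a dry-air penalty of 0.012/hPa above
  40 hPa summer VPDmax, and 0.05 per 100 W m⁻² of April SRAD deficit below
  450 W m⁻².  The base factor 0.90 represents a management shortfall common
  to all plots; it keeps the fraction of normalized yields above 1 "very
  few" (~7–8% at these conditions) while the binned upper decile still
  tracks the true frontier (recovered within ~3% across seeds).

What the generator does **not** emulate: spatially correlated weather
within years, soil and irrigation variation, cultivar-specific yield
levels, biennial bearing/carry-over effects, bloom phenology and pollinator
activity, and measurement error structure beyond i.i.d. noise.  Passing
tests therefore demonstrate that the pipeline's estimators are correct and
that planted signals of realistic size are recoverable — not that the same
effect sizes hold in field data.

## Numerical choices and degenerate inputs

* LI exactly on a bin edge joins the upper bin; upper-decile ties resolve
  by stable record order.
* The screen rejects constant columns (correlation undefined) with an
  explicit reason; |r| ties keep input column order, so an exact duplicate
  never displaces the original.
* RPIQ with zero RMSE is reported as +∞ and flagged.
* Seeds: a master seed hashes (SHA-256) into per-stage seeds below 2³¹, so
  adding a stage never perturbs earlier stages' randomness; all artifacts
  are byte-identical across reruns of the same config.
* Problem sizes in the shipped test-suite and acceptance script are chosen
  to keep a full run in minutes on one core: forests of 40–100 trees for
  cross-validation and interpretation (500 remains the library default),
  10-seed sweeps for recovery checks, and a reduced 6-orchard study for the
  byte-determinism check (determinism is scale-invariant).

## Known limitations

* The frontier is strictly linear through the origin; saturating or
  quantile-regression frontiers are out of scope.
* Pearson screening is linear and univariate; it is a parsimony device for
  interpretation, not a causal variable-selection procedure.
* The %IncMSE normalisation ("relative to the full model") is implemented
  as percent of the baseline out-of-bag MSE.
* Cross-validation at the plot-year level shares orchards between folds;
  the orchard-grouped mode gives more conservative error estimates when
  spatial generalisation is the question.
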