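# Methods

## The assessment problem

EU Member States must judge whether contaminants in fish and seafood for
human consumption exceed the maximum levels of Community legislation
(Marine Strategy Framework Directive, Descriptor 9). The difficulty is that
food-safety monitoring judges individual samples, while an environmental
assessment needs a statement about a whole marine subregion. This package
implements the two-part procedure used for the Italian Mediterranean
subregions: a *statistical range of acceptance* that converts a category's
measurement distribution into a single compliance decision, and a
GIS-style *fishnet integration* that aggregates station results to grid
cells under a precautionary majority rule.

## The statistical range of acceptance

Concentrations Y of one regulatory category are modelled as lognormal,
Y ~ LN(mu, sigma). The location is anchored at the data: mu = ln(gm),
where gm is the geometric mean of the observed concentrations. The
dispersion is fixed at "20%", for which two readings are implemented:

- **cv20** (default): the natural-scale standard deviation of Y is 20% of
  its median, i.e. a coefficient of variation of 0.2, giving
  sigma = sqrt(ln(1 + 0.2^2)) ≈ 0.19804 on the log scale. This reading is
  unit-free: expressing the data in µg/kg instead of mg/kg rescales the
  whole range consistently, and the decision is scale-equivariant (a
  property-tested invariant).
- **literal_log**: sigma = 0.2·|ln(gm)|, the literal "20% of mu" reading.
  It is unit-dependent and degenerate at gm = 1 (sigma = 0), so it is kept
  behind a flag for auditability and is never the default.

The regulatory threshold level TL plays the role of the distribution's
90th percentile: the fitted theoretical 90th percentile is
exp(mu + z₀.₉·sigma) with z₀.₉ ≈ 1.2816, and a data set **passes** when
its empirical 90th percentile does not exceed TL (ties pass — "must not
exceed" is read as ≤). The empirical quantile uses linear interpolation of
the ECDF by default; the estimator is selectable because near the boundary
the decision can depend on it. A Shapiro–Wilk test on ln(Y) checks the
lognormality assumption (subsampled to 5000 points with a fixed seed
beyond the test's validity range); a failed gate is *reported*, never used
to silently change the decision, because the procedure defines no
fallback. Constant data make the test undefined; the p-value is then NaN
and the gate reports not-OK.

When the fitted theoretical 90th percentile equals TL exactly, the
empirical 90th percentile at n = 200 falls below TL roughly half the time
(the empirical quantile is close to median-unbiased); the acceptance suite
verifies a pass rate in [0.40, 0.60] over 1000 replicates.

## Quality control and below-LOQ values

Record-level QC predicates (each can be disabled): coordinates inside the
assessment bounding box; record unit equal to the category unit; for
below-LOQ records, LOQ ≤ limit (a record whose quantification limit
exceeds the regulatory limit cannot inform the test); year inside the
assessment window. Filtering is total and fully accounted:
n_input = n_kept + Σ removals always holds.

Below-LOQ substitution is a genuine open choice in monitoring practice;
the default substitutes LOQ/2 (the common convention), with `loq`, `zero`
and `drop` available. The chosen policy is surfaced in the QC report so an
auditor can see it.

## Fishnet grid and integration

The grid is a regular net of square cells in ETRS89 geographic
coordinates with a 1:1 *angular* cell-size ratio. The nominal 50 km mesh
of the Mediterranean assessment is represented by an angular side length,
default 0.45° (~50 km meridionally at Mediterranean latitudes); it is a
parameter, not a metric constraint, since a degree of longitude shrinks
with latitude and no single angular size is exactly 50 km on both axes.
The origin defaults to the lower-left corner of the subregion's bounding
box and is overridable to reproduce an externally supplied net. Cells are
half-open, [lon0, lon0+d) × [lat0, lat0+d), with the net's outer top/right
boundary closed, so every point of the covered box belongs to exactly one
cell. A cell counts as part of the subregion when its rectangle
*intersects* the subregion polygon (boundary touch included); whether the
original assessment used intersecting or contained cells is not
documented, so the inclusive choice is made and stated here.

Each datum is coded 1 (within the limit, green) or 2 (exceeding, red),
with equality coding 1. Codes are integrated with one rule at every level
(datum → station, station-years → cell): the majority code wins and an
exact tie yields code 2, the precautionary principle. The source procedure
states the rule for cells only and merely names station-level integration;
applying the identical rule at every level is this package's design
choice, made for consistency and auditability. In whole-period mode a
station sampled in k years contributes k votes to its cell; single-year
mode restricts the assessment to one year. The "one out, all out"
alternative (any failing element fails the unit) is deliberately not
implemented.

Monotonicity holds by construction and is tested exhaustively to n = 12
and randomly beyond: flipping any constituent code from 1 to 2 can never
turn an integrated result from red to green.

## Summary statistics

Per subregion and category: spatial coverage (percentage of subregion
cells holding at least one assessed datum) and percentages within/outside
limits at the data, station and cell levels. Station denominators count
unique stations by default (station-years behind a flag — the original
tables do not say which they used). Percentages are rounded half-up to one
decimal, matching the precision of the published tables; counts are never
rounded; each within/outside pair sums to 100 ± 0.1 (rounding only).
Categories without data are reported as "-" and excluded from
denominators. Record counts per contaminant class (metals / PAHs / HOCs)
must sum to the grand total; the packaged reference counts of the Italian
campaign (5801+1086+232 = 7119 for the Adriatic, 1344+513+43 = 1900 and
5865+92+26 = 5983 for the western and Ionian/central subregions, 15002 in
all) exercise the same identity.

## Synthetic data generator

The real ~15000-record monitoring data set was never deposited, so a
generator reproduces the structure the method assumes: per-category
lognormal concentrations (median gm, natural-scale CV, default 0.2 — the
same dispersion the acceptance range assumes) at stations placed uniformly
inside a subregion polygon, optionally thinned toward the boundary to
mimic coastal monitoring effort. A category's exceedance fraction f is
dialled exactly: gm = TL·exp(−z₁₋f·sigma) makes P(Y > TL) = f; fractions
0 and 1 are mapped six sigma below/above TL. Three stylized synthetic
subregion polygons are packaged (an elongated basin, an L-shaped coastal
shelf, a basin with detached islands) so nothing is downloaded.

The default campaign is 60 stations sampled yearly 2006–2012, one record
per station-year, five categories mirroring the qualitative pattern of the
Mediterranean assessment: densely monitored metals with sporadic mercury
(3%) and lead (7%) exceedances, compliant cadmium in mussels, compliant
benzo(a)pyrene and dioxin+dl-PCB sums — 2100 records. That is a deliberate
desk-scale campaign: large enough for stable percentages and grid
coverage, small enough that the whole analysis reruns in seconds.

What the generator does *not* emulate — species-specific bioaccumulation,
trophic-level and size effects, seasonality, spatial autocorrelation of
contamination, analytical error structure — bounds what green tests mean:
they validate the statistics and the integration machinery, not the
ecological realism of any particular data set.

## Numerical choices

- Geometric mean via exp(mean(ln x)); any non-positive value is a hard
  error naming its index (zeros must be resolved by the LOQ policy first).
- Quantiles delegate to numpy's order-statistic estimators.
- Fishnet sizing uses ceil((extent/d) − 1e−9): the subtraction absorbs
  float noise when the extent is an exact multiple of d, while any real
  remainder still adds a covering row/column.
- File round-trips write floats with `repr` (shortest exact
  representation), making write → read lossless bit-for-bit and seeded
  outputs byte-identical.
- Each category's draws use an independent seeded stream
  (`SeedSequence([seed, plan_index])`), so adding a category never
  perturbs another's data.

## Known limitations

- The published subregion results (the Italian Tables' percentages) are
  not reproducible without the undeposited raw data; only their printed
  arithmetic identities and the regulatory catalog are checked exactly.
- The acceptance range treats each category in isolation: no covariates
  (species, season, size), no joint multi-contaminant model.
- Grid cells are angular, not equal-area; comparisons of cell counts
  across latitudes inherit that distortion.
- The ambiguity between anchoring the lognormal at the data's geometric
  mean (the procedure's definition) versus assuming the regulatory level
  *is* the 90th percentile of the data distribution (its summary
  description) is resolved in favour of the former; both percentiles are
  reported so either comparison can be read off.
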