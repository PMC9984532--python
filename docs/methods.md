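# Methods

This note documents the models, algorithms and numerical conventions
implemented in `sgakit`, the choices made where a convention had to be
fixed, and what the synthetic-data generators do and do not emulate.

## Colony-array screen scoring

### Data model

A screen consists of plates in 1536-colony format (32 rows x 48 columns
by default; any declared rectangular format is accepted). Each plate
carries several query alleles crossed to an arrayed gene-deletion
collection, with four technical replicates of each cross pinned in a
2x2 block and the blocks for the queries of one gene placed side by
side. The four outermost rows and columns hold dummy strains that absorb
the edge-growth advantage; they and any empty positions are assigned
missing values before any statistic is computed. A colony size of 0 is a
legal measurement (a dead cross), distinct from missing. Coordinates are
1-based, matching colony-quantification tools.

The replicate-block geometry (2x2) and the gene-to-plate assignment are
not dictated by the array format itself, so both are configurable in the
generator; the defaults are the most compact arrangement.

### Spatial correction

Colony arrays show smooth multiplicative gradients (nutrient access,
pinning pressure, plate position in the incubator). Each plate is
corrected independently by **median polish on log sizes** over the
experimental grid:

1. log-transform the present, positive experimental sizes (zeros take no
   part in the fit but survive division);
2. iterate row-median and column-median sweeps until the largest sweep
   update is below 1e-10 or 50 iterations;
3. gauge-fix: centre the log row and column effects to mean 0 over the
   rows/columns that carry data (geometric mean 1 in linear space), so
   the overall plate level stays in the data;
4. divide the plate by the fitted surface `exp(row_i + col_j)`.

Median polish was chosen because it is deterministic, exact on separable
multiplicative gradients, and — unlike least squares — robust to the
sick colonies the screen is designed to find. An optional second pass
smooths the polish residuals with a 7x7 moving median for non-separable
gradients; it is off by default because a residual smoother can absorb
real biology when replicate blocks are large relative to the window.
Correction is equivariant under global rescaling, and on noiseless
separable gradients removes them to better than 1e-6 relative error.
Caveat: when a plate carries very few gene bands, a 2x2 sick block is a
large fraction of a column and the column median partially absorbs it;
on realistically filled plates (>= 3 bands) the sweeps are robust to
isolated sick blocks. A plate with fewer than 50% of its experimental
positions present is rejected with advice to skip it.

After correction every plate is divided by the median of its present
values, so plates share a common scale with median exactly 1 (midpoint
convention for even counts).

### Fitness and interaction calling

Under the multiplicative null, double-mutant colony size is the product
of the single-mutant effects. Per replicate,

    fitness = normalized size / median(normalized sizes of that query
                                       across all genes and plates)

so a typical cross of each query has fitness 1. The per-query median is
global across plates (computing it per plate would re-absorb real
plate-level biology into the gauge). For each gene the query replicates
are compared with the wild-type-query replicates:

* **Replicate exclusion.** A replicate is excluded when its leave-one-out
  share of the sum of squared deviations, `1 - SS_without_i / SS`,
  exceeds 0.9. The leave-one-out form is used because the naive share
  `(x_i - mean)^2 / SS` cannot exceed 0.75 at n = 4 with three ties, so
  a 0.9 threshold would never fire. The rule runs in a single pass and
  excludes at most one replicate (the largest share); zero total
  variance excludes nothing. Note the rule is deliberately *not*
  iterated: re-applying it to the kept values can exclude again (with
  three survivors the leave-one-out share of the most distant point is
  often large), so exclusion-until-stable would frequently thin 4
  replicates to 2.
* **Test.** Two-sided Welch (unequal-variance) t-test on the surviving
  replicates; Welch is the safe default at 4-vs-4 where a sick cross can
  have inflated variance. If either side has fewer than 3 survivors the
  gene is *untestable* (statistics reported as missing). If both sides
  have zero variance, p is 1 for equal means and 0 otherwise.
* **Multiplicity.** Benjamini-Hochberg step-up adjustment per query
  across all of that query's genes (the family a screen reader actually
  scans); missing p-values pass through and do not count toward the
  family size.
* **Hit call.** Synthetic sick iff `fitness_ratio < 0.8` (strict) and
  BH-adjusted `p < 0.05` (strict), where the ratio is the mean of the
  surviving query replicates over the mean of the surviving wild-type
  replicates. A raw-p mode exists for sensitivity analysis.

**Power at these settings.** The test suite measures, on synthetic
screens (200 genes, 10% true interactions at ratio 0.5, lognormal noise
sigma = 0.15, 4+4 replicates), mean recall ~0.6 at mean precision ~0.98.
This is a property of the method, not a bug: the per-gene effect size is
ample (|t| ~ 6), but a 4-observation variance estimate gives the Welch
statistic ~4 degrees of freedom, and the BH threshold at 10% prevalence
is p ~ 0.005, so the noncentral-t miss probability is substantial.
Recall above 0.9 at this noise level would require sharing variance
information across genes (a moderated t in the limma style), which the
plain per-gene t-test deliberately does not do. At sigma = 0.1 the same
configuration detects ratio-0.5 interactions near-certainly, and the
null calibration (no injected interactions) yields median fitness
ratios within [0.99, 1.01] and a false-call fraction of ~0.03%.

### Hit-set post-processing

* **Venn regions**: exclusive membership-region counts over the hit sets
  of k >= 2 queries; counts sum to the union size.
* **Linkage exclusion**: genes genetically linked to the query locus
  co-segregate with the query marker during the cross and score as
  spuriously sick. A hit is excluded when it lies on the locus
  chromosome and the distance from the locus to its nearest gene
  boundary is strictly below the window (default 75 kb — roughly the
  scale over which meiotic linkage distorts segregation in budding
  yeast; configurable, since no canonical value exists). A gene spanning
  the locus has distance 0.
* **Enrichment**: for each user-supplied flattened gene set,
  p = P(X >= k) with X hypergeometric (population = screened universe,
  successes = set members in the universe, draws = hit list). Terms are
  ranked by raw p with a top-N selector (default 10), as conventional
  for enrichment reporting; a BH column is included for convenience.
  Ontology structure and annotation content are inputs, not code.

## Fluctuation-assay mutation rates

Parallel cultures grown from small inocula are plated on selective
medium; mutant counts fluctuate wildly because mutations arising early
found large resistant clones ("jackpots"). The estimator has three
steps, applied per culture:

1. **Plating bookkeeping.** Observed colonies are scaled back to mutant
   cells per culture:
   `r = culture_vol x (conc_factor x colonies / plated_vol x dilution)`.
2. **Lea-Coulson correction.** The implicit median relation
   `r = M (1.24 + ln M)` converts the mutant count r into the number of
   independent mutation events M. The forward map is strictly increasing
   for `M > exp(-1.24)` and crosses zero there, so for r > 0 the root is
   unique; it is bracketed at `[exp(-1.24), max(r, 10) x 10^k]` (the
   upper end grown geometrically until it encloses the root) and solved
   with Brent's method to `|forward(M) - r| <= 1e-10`. r = 0 maps to
   M = 0 (limit convention) and is flagged, since the correction has no
   information in a zero count; the zero-count (P0) estimator is out of
   scope.
3. **Rate.** `rate = M / total cells in the culture`.

The cohort is summarized by the **median rate with an exact 95%
confidence interval from binomial order statistics**: the tightest pair
of order statistics `(x_(l), x_(u))` whose exact coverage
`P(l <= B <= u-1)`, `B ~ Binomial(n, 1/2)`, reaches 0.95 (ties broken by
symmetry). For n < 8 no pair reaches 95%; the full sample range is then
returned (actual coverage `1 - 2^(1-n)`), rather than failing. The
correction is applied per culture by default, following the equation
sequence; the classical method of the median (one correction applied to
the median r) is available as `mode="median-r"`. The per-culture mode
behaves like the method of the median at the cohort level — the median
of per-culture M equals the inversion of the median r by monotonicity —
while also exposing per-culture rates.

The test suite verifies that on simulated cohorts (true rate 1e-7 per
cell division, 10^3 -> 10^8 cells, 14 cultures) the cohort median is
within a factor of 2 of the truth in >= 90% of cohorts, and that the
forward/inverse round trip is accurate to 1e-8 relative over
M in [0.3, 1e6]. Not modelled: mutant/wild-type fitness differences,
phenotypic lag, cell death, and maximum-likelihood (Ma-Sandri-Sarkar)
estimation.

## Growth curves and doubling time

OD600 time series are fitted in their exponential phase with
`y = Y exp(Bx)` by ordinary least squares of ln(OD) on time. Because
"the linear range" is a judgment call when done by eye, the window is
chosen automatically: among all runs of >= 4 consecutive readings with
OD inside [0.05, 0.5], every sub-window is scored and the longest window
with r^2 >= 0.99 wins, ties broken by higher r^2; if no window reaches
the threshold the best-r^2 candidate is used and flagged. Band, minimum
length and threshold are configurable.

The population doubling time is `PD = 0.6931 / B x 60` minutes. The
constant 0.6931 is the rounded natural log of 2 used by the downstream
reporting convention and is applied verbatim so printed values match
that convention exactly; `exact_ln2=True` switches to full precision
(a 2e-5 relative difference). B <= 0 leaves PD undefined and flagged.

A caution the test suite makes explicit: on a logistic curve the
per-capita rate is `B (1 - OD/K)`, so when the carrying capacity is
close to the fitting band (e.g. K = 1 with a band up to 0.5) *any*
windowed exponential fit reports materially less than the nominal B —
at OD = 0.5 the instantaneous rate is already B/2. Rate-recovery
accuracy is therefore validated with K well above the band; with K near
the band the suite asserts the predicted underestimation instead.

## Synthetic-data generators

All generators draw every stochastic quantity from a single
`numpy.random.default_rng(seed)`, so one integer seed reproduces a
dataset byte-for-byte.

* **Screens.** Colony size = 300 (arbitrary units) x query fitness x
  gene fitness x interaction x spatial surface x `exp(N(0, sigma^2))`.
  The spatial surface is a separable row x column field built from one
  sinusoidal mode per axis (geometric mean 1, log-amplitude ~0.1-0.2 —
  gradients of the magnitude colony arrays actually show). Border
  dummies follow the same model at fitness 1. Defaults match the study
  conditions: 4 technical replicates in 2x2 blocks, 4-deep dummy
  border, lognormal noise sigma = 0.1 (null calibration) or 0.15
  (recovery). Not emulated: pinning robotics, neighbour competition,
  image segmentation, non-separable gradients (available in the data
  model but not injected by default), and agar-batch effects. Passing
  tests on these screens therefore demonstrate correctness of the
  scoring arithmetic and calibration under the model's own assumptions,
  not robustness to every artefact of real arrays.
* **Fluctuation cohorts.** Growth proceeds by generations from N0 to
  N_final (a partial final generation handles non-power-of-two ratios).
  Each generation contributes `Poisson(mu x cells produced)` new
  mutation events; every mutant clone then expands deterministically
  with the culture — exactly the no-death, equal-fitness assumptions of
  the Lea-Coulson estimator, which is the point: the generator tests the
  estimator under its own model. The plated aliquot receives a
  `Binomial(r, plated fraction)` subsample. The heavy-tailed jackpot
  signature (cohort maximum far above the cohort median) is asserted by
  the suite.
* **Growth curves.** Logistic trajectories
  `K / (1 + (K/x0 - 1) exp(-rate x t))` sampled at a fixed interval with
  additive Gaussian read noise (floored at 0). Default read noise in
  tests is 0.0025 OD — typical microplate-reader precision; at 0.01 the
  relative noise at the bottom of the fitting band (OD 0.05) already
  exceeds the 5% accuracy being verified.

## Numerical conventions

* Missing values are NaN in memory and `NA` on disk; medians ignore
  them; even-count medians use the midpoint of the central order
  statistics.
* Result tables render numerics with 12 significant digits, so write +
  read reproduces every value to at least 10 significant digits.
* Median polish: tolerance 1e-10 on the largest sweep update, cap 50
  iterations (exact decompositions converge in one sweep).
* Brent inversion: bracket `[exp(-1.24), max(r, 10)]` with geometric
  expansion, `xtol = 1e-15`.
* BH adjustment delegates to statsmodels' step-up implementation;
  enrichment ties in p are broken by term name for deterministic output.

## Problem sizes in the test suite

Simulation-backed checks use 20 screens of 200 genes (two queries, 4+4
replicates, two 1536-plates each) for calibration/recovery, 50 cohorts
of 14 cultures for fluctuation recovery, and 20 seeds for growth-rate
recovery. These sizes give stable pass/fail behaviour for the asserted
bounds while keeping the whole suite fast enough to run on every change.

## Known limitations

* The spatial correction is not claimed to be equivalent to any specific
  published array-correction tool; equivalence is claimed only with the
  removal of injected separable effects on synthetic plates.
* Per-gene t-tests at 4 replicates have limited power at high noise (see
  the power paragraph above); the pipeline reports effect sizes
  (fitness ratios) alongside p-values so marginal sick genes remain
  visible to follow-up.
* The linkage window and the replicate-block geometry are conventions,
  not measurements; both are configurable and recorded in outputs.
* Positive (alleviating) interactions are not called; only synthetic
  sickness is thresholded.
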