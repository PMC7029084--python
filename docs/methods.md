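# Methods

This note records the statistical models behind `lhinvar`, the defaults
and why they were chosen, the numerical choices, and the known limits of
what the synthetic-data tests demonstrate.

## Data model

A trait table holds one row per species: a taxonomic group label, adult
body mass in grams, and positive trait values in declared units.  All
statistics operate on log₁₀-transformed values, so zeros, negatives and
non-numeric cells are recorded as missing (with a warning) rather than
rejected; rows are never dropped on read.  Species names are matched to
tree tips exactly after trimming and collapsing whitespace — no synonym
resolution, so joins are deterministic.  Tables with per-source minimum
and maximum columns are harmonized by arithmetic mean (single present
value passes through; a reversed pair is averaged with a warning, since
the mean is order-insensitive).  Duplicate species are a hard error: the
table is assumed pre-averaged across sources, and silent averaging would
hide provenance decisions that belong in data preparation.

## Criterion 1 — variance ratio

Within an analysis group, raw trait and mass values are divided by their
group medians, log₁₀-transformed, and their sample variances (n − 1
denominator) compared: ratio = mass variance / trait variance, pass if
ratio > 1.  Two deliberate details:

- Division by the median is exactly a constant shift of the logs, so it
  cannot change the variances; the code asserts this identity on every
  call (tolerance 1e−9 relative).  The normalization is kept because the
  *reported* normalized variances are the unit-comparable quantities, and
  because it makes the procedure robust to future variants that normalize
  on the raw scale.
- The mass variance is computed over **all** species in the group with a
  recorded mass, not the per-trait complete-case subset.  A group
  therefore has a single mass variance, and ratio × trait-variance is
  constant across traits within a group — a useful internal-consistency
  check that the tests exploit.

## Criterion 2 — unimodality and coverage

The dip statistic — the smallest sup-norm distance between the empirical
CDF and the class of unimodal CDFs — is implemented from scratch via the
classic iterative greatest-convex-minorant / least-concave-majorant
algorithm (no dip implementation exists among this package's
dependencies).  It is validated in the test suite against an independent
linear-programming oracle that solves the defining optimization directly
on small samples: for a piecewise-linear unimodal CDF with knots at the
data points it suffices to try each data point as the mode, which gives
one small LP per mode.  The two routes agree to ~1e−13 on random uniform,
normal and two-cluster samples.

P-values are Monte Carlo against the uniform null (the least favourable
unimodal distribution): p = (1 + #{null dips ≥ D}) / (n_mc + 1), default
n_mc = 10,000, seed recorded in every result.  The continuity correction
keeps p > 0 and makes the test slightly conservative, which suits the
framework's intent (the null is "no departure from unimodality").  A
calibration run (n = 50, 500 replicates of 2,000 null draws) puts the
type-I error within two Monte-Carlo standard errors of α = 0.05.  The
minimum sample size is 4 (configurable).  With numba present the inner
loop is JIT-compiled (~3 µs per dip at n = 50); the pure-Python fallback
is identical in results.

Coverage is the percentage of log₁₀ values within mean ± 2 sample SDs,
boundary inclusive, sd with n − 1 denominator.  Pass at ≥ 95.0; strictly
above 94.0 is "marginal" and rendered "(+)".  Marginal promotes to a
type I pass only under an explicit `lenient_marginal` flag (default off):
the judgment is made visible rather than silent.  Chebyshev-type bounds
guarantee coverage ≥ 75% for any sample, which the result type asserts.

## Criteria 3/4 — OLS and PGLS

OLS (via statsmodels) and PGLS of log₁₀ trait on log₁₀ mass.  Type II
requires the conjunction: OLS slope p ≥ 0.05, PGLS slope p ≥ 0.05, and
OLS R² < 0.05 — the most conservative reading of the framework.

PGLS model: errors ~ N(0, σ²·W(λ)) where V is the Brownian-motion
covariance of the pruned tree (V_ij = shared root-to-tip path length; a
stem retained from pruning counts as shared history of all tips, which
makes pruning commute exactly with taking the covariance sub-block) and
W(λ) multiplies V's off-diagonals by Pagel's λ.  On non-ultrametric trees
tips have unequal depths; fixing tip residual variances proportional to
depth is the standard BM-consistent correction, and algebraically
D^{1/2} R(λ) D^{1/2} with R the BM correlation matrix equals the
λ-scaled V — so the default "depth" weights mode is exactly W(λ) above.
A "uniform" mode (W = λ-scaled correlation matrix, equal tip variances)
is provided; with λ = 0 it reproduces OLS to machine precision, a limit
the acceptance checks verify.

λ is estimated by maximizing the profile log-likelihood (β and σ²
profiled out) on a 51-point grid over [0, 1], refined by bounded scalar
minimization between the grid neighbours of the optimum (xatol 1e−6).
ML is the default, REML selectable.  Bounds default to [0, 1] for
interpretability; estimates at a bound are flagged.  Coefficient CIs and
slope p-values are t-based with n − 2 degrees of freedom, conditional on
λ̂ — the usual practice in comparative methods; this ignores λ-estimation
uncertainty, and simulation (b = 0.3, λ = 0.8, n = 150, 200 replicates)
puts the realized 95% CI coverage near 96% with slope bias ≲ 0.001.
Zero-length terminal branches (which make V singular) are perturbed by
1e−8 × tree depth, far below reporting precision.  Regressions with fewer
than 8 complete pairs are reported as not available (configurable); this
reproduces the "sample too small" behaviour expected for df ≈ 5.

On the criterion numbering: report columns attach the slope tests to
"criterion 3" and R² to "criterion 4", the ordering conventionally used
in tabulated applications of this framework (both conventions circulate;
the tabular one is used so that reports can be read against existing
result tables).

## Criterion 5 — SMA isometry

SMA slope = sign(r)·SD_y/SD_x, intercept through the means, CI via the
F-based factor B = F(0.95; 1, n−2)(1−r²)/(n−2),
CI = slope·(√(B+1) ± √B).  This interval is exactly reciprocal under
swapping x and y, so the isometry verdict (significant correlation and
1 ∈ CI) is swap-invariant — asserted numerically in the tests, along with
|OLS slope| ≤ |SMA slope| (equality iff |r| = 1).  The pair scan fits all
unordered trait pairs with ≥ 5 complete cases (earlier trait in config
order is x) and lists smaller pairs as skipped with the reason.  No
phylogenetic correction is applied to SMA, matching standard practice for
this criterion; a phylogeny-informed reduced major axis would be the
natural improvement and is deliberately out of scope.

## Verdict aggregation

type I = criterion 1 pass AND unimodality pass AND coverage pass
(marginal only under the lenient flag); type II = the three-way
conjunction above; type I+II = both.  A missing ingredient (insufficient
sample, no usable tree) propagates as "not available" rather than a fail;
a missing PGLS blocks type II unless an OLS-only degraded verdict is
explicitly enabled.  Verdicts are monotone: promoting any single
criterion from fail to pass can never demote a verdict (property-tested
over all mark combinations).  Reports regenerate byte-identically from
identical inputs and config, with seeds in the footer.

## Synthetic data

Trees: Yule (pure-birth) trees via dendropy, extended past the n-th birth
by the exponential waiting time to the next (censored) event so terminal
branches are never zero by construction; optional lognormal jitter of
terminal branches produces non-ultrametric trees for exercising the depth
weights.  Body mass: i.i.d. log-normal by default — log₁₀ M ~
Normal(1.0, 0.78²), i.e. masses of a few to a few hundred grams with
log-variance ≈ 0.6, the spread typical of broad amphibian compilations —
deliberately independent of the tree so that criterion behaviour is not
confounded with mass signal (evolving mass on the tree is a separate
option).  Traits: allometric (log₁₀ T = log₁₀ a + b·log₁₀ M + ε with
ε ~ MVN(0, σ²·λ-scaled BM covariance normalized to unit mean depth, so σ
is a tip SD regardless of tree height)); invariant (i.i.d.
Normal(log₁₀ a, σ²)); bimodal (equal mixture of two invariant components
separated by 5σ by default).  Missingness masks entries independently per
trait at a stated rate.  Everything is reproducible from a single seed.

What the generator does *not* emulate: measurement error and
source-heterogeneity in compiled tables, taxonomically structured (non-
random) missingness, correlated evolution between traits beyond shared
mass dependence, extinct lineages, and trees with calibration error.
Passing the synthetic suite therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to these
real-data features.

## Known limitations

- **The 95% coverage rule sits on a knife edge.**  For a genuinely normal
  trait the expected fraction within ±2 SD is 95.45%, barely above the
  95% threshold; at n = 200 a perfectly invariant normal trait passes the
  strict rule in only ≈ 78% of samples (≈ 90% with the marginal band).
  End-to-end classification accuracy of a true invariant trait is capped
  accordingly — the acceptance suite measures ≈ 73% for the full strict
  type I+II chain at n = 200 — and this is a property of the criterion
  itself, not of the implementation.  Larger samples do not escape the
  cap (the pass probability converges to ≈ 68% as n grows); only a
  coverage threshold below the normal expectation (e.g. 94%) or a
  band wider than ±2 SD would.  The thresholds are configurable for
  exactly this reason, but defaults follow the framework as stated.
- The dip test's Monte-Carlo p-values depend on seed and n_mc; published
  dip p-values obtained by other methods (table interpolation) will agree
  only approximately.
- λ̂ to two decimals is optimizer-dependent; values reported by other
  toolchains may differ in the last digit, and λ estimation uncertainty
  is not propagated into slope CIs.
- Exact reproduction of published regression tables additionally requires
  the original data deposit and source phylogeny; with those inputs the
  pipeline applies the same operations those tables describe.
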