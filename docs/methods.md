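# Methods

## The analysis model

The pipeline treats birth month as a 12-level categorical exposure and each
diagnosis code as a binary outcome defined by code presence: a patient is a
case for a condition if the mapped code appears at least once in their
record, and every other cohort patient is that condition's control. No
covariate adjustment is performed — the scan is a deliberately simple
marginal screen, and patients contribute to every condition they carry.

**Relative-risk curve.** For month `m`, `RR_m` compares the case rate among
patients born in `m` with the case rate among patients born in any other
month (not with the overall mean). This choice keeps each month's RR an
ordinary two-group risk ratio, so the Katz log-scale confidence interval
applies directly and a "max RR" per condition is well defined. When a
month's 2×2 table contains a zero cell (no in-month or no out-of-month
cases), 0.5 is added to all four cells of that month's table only
(Haldane–Anscombe); unaffected months keep their exact values. Curves are
therefore always finite and strictly positive, which the permutation stage
relies on.

**Association test.** The per-condition omnibus statistic is the Pearson
chi-squared test on the 2×12 case-status × birth-month table, df = 11.
Months with zero cohort population are dropped with df reduced; a table
with fewer than two populated months, or with no cases (or all cases), is
an error rather than a silent zero. The chi-squared choice is this
package's normative decision: it is the simplest omnibus test of
month-by-status association, and the scan's contract (a raw p per tested
condition, FDR-adjusted across the tested set) does not depend on it.

**Multiplicity.** Benjamini–Hochberg step-up adjustment is applied across
exactly the conditions passing the inclusion threshold in the same scan
(each institution adjusts over its own tested set, not over the shared
subset). The threshold is inclusive: a condition with exactly the minimum
case count is tested. The default minimum of 1000 cases reflects the scale
at which monthly counts (~80+ expected cases per month) make the
chi-squared approximation and the RR intervals well behaved.

**Replication statistic.** Pattern replication between institutions is the
Pearson correlation between the two month-ordered 12-point RR curves,
tested against an empirical null obtained by shuffling the 12 entries of
one curve as a block (uniform random permutation, sampled without
replacement) while the other is held fixed. The empirical p is the
proportion of permuted correlations *strictly greater* than the observed
one out of B draws; with the default B = 1000 an exact zero is displayed as
`p < 0.001`, matching the floor of resolution. A `(b+1)/(B+1)` variant is
available (`add_one=True`) but off by default. Permuting the curve, rather
than re-simulating patients or resampling with replacement, preserves the
multiset of RR values and tests exactly "is this month-assignment pattern
special". By default institution A's curve is fixed and institution B's is
shuffled; the roles can be swapped for a symmetric report.

One numerical subtlety is load-bearing: the observed and permuted
correlations are computed through the identical per-row arithmetic path
(elementwise reductions, no matrix product), so the identity permutation is
bit-equal to the observed correlation and can never be counted as an
exceedance under the strict inequality. BLAS matrix products round
differently depending on matrix shape and were measurably biasing small
exact p-values before this was fixed.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `min_patients_per_condition` | 1000 | inclusion threshold (inclusive) per institution |
| `fdr_alpha` | 0.05 | phenome-wide FDR level |
| `ci_level` | 0.95 | RR confidence-interval coverage |
| `n_permutations` (B) | 1000 | permutation draws per condition |
| birth-year window | 1926–2000 | inclusive cohort filter |

Sub-seeds for per-condition permutation runs are derived from a SHA-256
hash of (master seed, condition code), so replication p-values are
independent of condition iteration order and stable under list reshuffling.

## The synthetic cohort generator

The generator emulates the *structure* of a two-hospital EHR extract: a
patients table (birth month/year, demographic categories), a long
diagnosis table with one row per (patient, condition), and a ground-truth
table. Injected effects act multiplicatively on probability,
`p(m) = p0·(1 + A·cos(2π(m−φ)/12))`, so the true monthly multiplier curve
is on the same scale as the estimated RR curve (to first order in `p0`),
and `p0` is the exact marginal prevalence under uniform births because the
cosine sums to zero over twelve months. Custom 12-point multiplier curves
(mean 1) are supported for non-sinusoidal effects.

Defaults are chosen to look like a large urban cohort: uniform birth-month
marginal (configurable, since real monthly birth rates are mildly
seasonal), birth years 1926–2000, a single sex attribute at 58/42
proportions with a small "other" category. Null conditions cycle
prevalences through {0.001, 0.005, 0.01, 0.05, 0.1} so that, at the cohort
sizes used in the tests, some null conditions fall on each side of the
1000-case inclusion threshold. The two-site designs are: `shared`
(identical effect specs, independent patients), `independent` (site B
redraws each peak month uniformly on 1..12 and each amplitude uniformly on
[0.02, 0.15], spanning max-RR values of roughly 1.02–1.17, i.e. the weak
effects a phenome-wide scan must resolve), and `null` (all amplitudes
zero).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: visit-level longitudinal structure, healthcare-
process and documentation biases, diagnosis-code error, comorbidity
correlation between conditions, and non-stationary birth-month
distributions across birth cohorts. Conditions are sampled independently
per patient, so phenome-wide calibration results here assume independent
outcomes, which real comorbid conditions violate.

## Study sizes used in the test suite

The statistical acceptance tests run the pipeline at sizes chosen to make
the checked properties sharp while keeping the suite quick: null
calibration uses 100,000 patients × 50 null conditions × 20 seeds; effect
recovery uses one cosine effect (p0 = 0.05, A = 0.10, January peak) in
500,000 patients × 20 seeds (theoretical max RR ≈ 1.110, estimated mean
falls in [1.05, 1.18]); replication power uses two 200,000-patient sites ×
20 seeds at B = 1000. The acceptance script's study uses two 200,000-
patient sites, nine injected effects and 41 nulls.

## Numerical and degenerate-input choices

- Arg-extremum months of an RR curve tie-break to the earliest calendar
  month (deterministic reporting).
- `benjamini_hochberg` delegates to statsmodels' `fdr_bh` behind the
  package's own validated surface; tests pin it against a literal
  step-up implementation.
- FDR-adjusted p-values of exactly zero are clipped to the smallest
  positive float for Manhattan `−log10` heights, with a logged note.
- Zero-variance (constant) risk curves make the Pearson correlation
  undefined; such conditions are excluded from replication output with a
  logged reason rather than poisoning the batch.
- Demographics comparison pools "Unknown"/"Unidentified"/"Declined" and
  any category recorded at only one site into a single "unknown" bucket
  per attribute (case-insensitive matching) before the 2×k chi-squared
  test; attributes left with fewer than two categories are skipped.
- Readers collect all malformed rows (with line numbers) before raising,
  so a dirty file produces one actionable error; duplicated patient ids
  with conflicting birth fields are a hard error.

## Known limitations

- **The permutation test calibrates against exchangeability, not
  independence.** When both institutions carry *smooth* seasonal effects
  that are independent of each other, their phase offset lands within ±1
  month by chance 3/12 of the time, producing high curve correlations that
  the month-shuffling null cannot explain; measured rejection at the 0.05
  level is then well above nominal (≈ 0.35 under the generator's
  independent-effects prior at 200,000 patients per site). A significant
  replication p therefore means "the two curves share a seasonal pattern",
  not "the institutions' effects are causally linked" — two sites with
  independent but similarly-phased seasonality will replicate. Under a
  true exchangeable null (no seasonal structure, or one curve genuinely
  unstructured) the test is calibrated, as the null-calibration tests
  verify.
- Monthly RR curves from a common cohort share the denominator, so the 12
  RRs are not independent; the permutation null treats the curve as given
  and does not model this estimation noise.
- The normalized per-month rate curve of a generated condition converges
  to the injected multiplier curve at the binomial Monte-Carlo rate
  (per-month SE ≈ 1.5% of the mean at p0 = 0.05, n = 10⁶); convergence
  tests bound each month's deviation by 4 binomial SEs.
- With the treatment-era filter, only a `service_year` column is honoured;
  full visit tables are out of scope.
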