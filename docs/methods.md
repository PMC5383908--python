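# Methods

## Model and estimator

The repeated-measures correlation quantifies the common intra-individual
linear association between two paired measures.  The estimator is an
ANCOVA with an unusual role assignment: the participant identifier is
the categorical factor (absorbing all between-participant variation in
level) and one measure is the continuous covariate.  The fitted model is

    measure1_ij = mean1_j + beta * (measure2_ij - mean2_j) + eps_ij,

a varying-intercept, common-slope fit.  Parallel lines are not an
*assumption* being imposed — the common slope is exactly the quantity
under test; when individual slopes are heterogeneous the shared-slope
effect size is small with wide intervals, which is the correct answer to
the "common association" question.  Which measure plays response and
which covariate is immaterial: only the sums of squares change, not
r_rm, beta's sign, F, p or the CI (enforced by a symmetry test).

Rather than materializing N − 1 dummy columns, the fit uses
within-group centering: with x_c = x − x̄_j, y_c = y − ȳ_j pooled over
participants and S_xx, S_yy, S_xy their sums of squares/products,

    beta       = S_xy / S_xx
    SS_measure = S_xy^2 / S_xx
    SS_error   = S_yy − SS_measure
    r_rm       = sign(beta) * sqrt(SS_measure / (SS_measure + SS_error))
               = S_xy / sqrt(S_xx * S_yy)

This is algebraically identical to the dummy-coded least-squares solve
(verified against one in the tests to 10+ significant digits) and stays
stable to at least N ~ 10^4 participants, since no N-wide matrix is ever
formed.  Contrast coding therefore never arises; the decomposition is
coding-invariant by construction.

Significance: F = SS_measure / (SS_error / df) against F(1, df) with

    df = N(k − 1) − 1  =  L − N − 1,

where L is the total row count and k = L/N the mean number of paired
observations per participant.  For unbalanced data L − N − 1 (the exact
rank-based quantity) is used throughout; N(k − 1) − 1 with fractional
k = L/N equals it identically.  The upper-tail F probability equals the
two-sided t test on beta and is reported as the two-sided p-value for
the correlation.  The approximation (k − 1)(N − 2) is provided
(`approx_df`) for quick power lookups; its ratio to the exact df tends
to 1 as N grows.

### Numerical edge cases

- **Perfect fits.** When the residual sum of squares falls below
  1e−12 × S_yy it is snapped to exactly 0, so noise-free parallel-line
  data report r_rm = ±1 exactly rather than 1 − 1 ulp (F = ∞, p = 0).
- **Exact null.** beta == 0 (exactly) reports r_rm = +0, F = 0, p = 1;
  no sign is meaningful there.
- **Degenerate designs.** If *no* participant has within-participant
  variance in the covariate the fit raises a degenerate-design error.
  Individual constant-covariate participants are retained — they simply
  contribute nothing to beta.
- **Minimal designs.** N = 2, k = 2 (df = 1) fits, but no analytic CI
  exists for df < 2; the vacuous interval [−1, 1] is reported with a
  warning.

## Data model

Long format, one row per observation: participant label, measure 1,
measure 2.  Cleaning rules (applied by the loaders, idempotent):

- a row missing either measure (or the id) is dropped whole;
- participants left with fewer than 2 complete pairs are dropped with a
  warning (a single pair carries no within-participant information and
  would distort k and df);
- identifiers are opaque labels compared by value after string
  normalization (3, 3.0 and "3" are the same participant); first
  appearance fixes factor-level order;
- duplicated identical rows are retained (legitimate repeated
  observations) with an informational note;
- after filtering, N ≥ 2 and L − N − 1 ≥ 1 are required.

CSV (or TSV) with a header row, '.' decimals, UTF-8; floats are written
at full precision and read back with round-trip parsing, so write→load
reproduces a dataset exactly.  Wide-format input is out of scope —
reshape first.

## Confidence intervals

**Analytic.** Fisher transformation z = arctanh(r_rm) with standard
error 1/sqrt(df − 1) — the Pearson 1/sqrt(n − 3) convention with the
rmcorr df substituted for n − 2 — back-transformed by tanh and clipped
to [−1, 1].  From the published rounded example inputs (r_rm = −0.70,
df = 71 and r_rm = −0.41, df = 32) this reproduces the corresponding
printed intervals to within ±0.015 per endpoint, the agreement
attainable from rounded point estimates.

**Bootstrap.** Observations are resampled with replacement strictly
*within* each participant; every participant keeps their own number of
rows and participants are never dropped or mixed, so the
repeated-measures structure of the design is preserved in every
resample.  The interval is the percentile interval (endpoints are order
statistics of the resampled r_rm values); the central estimate
r_rm_boot is the median.  These are deliberate choices the method
leaves open: percentile over BCa for simplicity and transparency, the
median as a robust central summary.  Degenerate resamples (no
within-participant covariate variance anywhere) are redrawn, capped at
100 retries, then an error is raised.  Everything is reproducible from
the seed.  Measured coverage at the reference conditions below: 95.4%
for nominal 95%.

## Power

Power is computed from the Pearson-correlation machinery with the
rmcorr df substituted in (df = N(k − 1) − 1 for k ≥ 2; k = 1 denotes
the ordinary Pearson design with df = N − 2).

- `power_analytic` evaluates the exact noncentral-t power of the
  two-sided test of rho = 0: ncp = rho·sqrt(df + 1)/sqrt(1 − rho²),
  critical value t_{alpha/2, df}.  This is the computation behind
  standard correlation power software, it returns alpha exactly under
  the null, and it agrees with large Monte-Carlo runs to within a
  fraction of a Monte-Carlo standard error.
- `power_fisher_z` is the lighter normal-approximation formula
  Phi(|arctanh rho|·sqrt(df − 1) − z_{1−alpha/2}) + (other tail).  It
  converges to the exact value as df grows but is visibly conservative
  for large effects at small df (e.g. 0.923 vs 0.946 at rho = 0.5,
  N = 20, k = 3), which is why it is not the default; it also serves as
  the fallback where scipy's noncentral t loses accuracy at very large
  df.
- `power_simulated` is the independent Monte-Carlo check: generate at
  the requested within-correlation, fit, count rejections; it returns
  the estimate with its binomial standard error.

`power_curves` tabulates and draws the power family (defaults: effect
sizes 0.10/0.3/0.50, k ∈ {1, 2, 3, 5, 10}, 80% reference line).  The
k = 2 curve is asymptotically equivalent to the k = 1 Pearson curve
(df N − 1 vs N − 2), and power grows quickly in both N and k.

## Synthetic data generator

`SimulationSpec` realizes the varying-intercept/common-slope model as a
generative process: participant covariate centers x̄_j ~
Normal(0, between_x_sd²); response centers ȳ_j = between_trend·x̄_j +
Normal(0, intercept_sd²); within-participant covariate values are
deterministic equispaced symmetric offsets around x̄_j (optional
Gaussian jitter available); responses y_ij = ȳ_j + slope·(x_ij − x̄_j)
+ Normal(0, noise_sd²).  The implied within-participant correlation is

    rho_w = slope·s / sqrt(slope²·s² + noise_sd²),   s = within_x_sd.

Two calibration details matter:

- **Centered-spread scaling.**  The deterministic offsets are scaled by
  sqrt((k − 1)/k) so their spread equals the *expected centered spread*
  of a random covariate sample.  Within-group centering shrinks random
  residuals by exactly that factor but would leave deterministic
  offsets untouched; without the scaling the fitted r_rm converges
  above rho_w and simulated power overshoots the df-based analytic
  value.  With it, r_rm is a consistent estimator of rho_w (measured
  bias −0.002 at rho_w = 0.5, N = 100, k = 10) and the analytic and
  simulated power paths agree.
- **Noise only on the response.**  Noise-free specs are exactly
  collinear per participant, which makes the didactic fixtures exact.

Defaults (N = 20, k = 5, rho_w = 0.5 via slope 0.5, unit covariate
spread, noise sqrt(0.75)) describe a moderate repeated-measures design
typical of the studies the estimator targets, and are the conditions at
which bootstrap coverage is validated.

What the generator deliberately does **not** emulate: non-Gaussian or
heteroscedastic errors, participant-varying slopes, autocorrelated
occasions, missing-data mechanisms, or measurement unreliability in the
covariate.  Passing tests therefore certify the estimator and its
inference under the homogeneous-slope Gaussian model, not robustness to
those violations.

### Didactic fixtures

`figure2_grid` crosses the within-participant correlation (columns:
exactly −1, 0, +1) with the between-participant trend (rows: negative /
none / positive).  The constructions are integer-valued so the labeled
correlations hold *exactly* in floating point: odd symmetric integer
offsets u give the ±1 columns (residual SS exactly 0), and the zero
column uses the even-symmetric integer pattern w = k·|u| − Σ|u|, which
has zero sum and is exactly orthogonal to u, making the within
cross-product Sxy exactly 0.  Covariate centers 4 apart with trend
slopes ±2 let the between-participant variation dominate the pooled OLS
slope, producing exact Simpson's-paradox panels (e.g. within +1, trend
negative: every participant's line rises, the pooled line falls).  The
grid needs N ≥ 3 and ≥ 3 points per participant (with 2 points the
zero-column pattern would be constant).

`figure3_fixtures` returns a base dataset plus two linear transforms —
the covariate globally mapped to x/2 + 1, and one participant's
response shifted by −2 — whose fits agree to machine precision,
demonstrating invariance of r_rm and p under positive linear maps and
per-participant shifts.  (A negative scaling of exactly one measure
flips only the sign.)

## Visualization

`rmcorr_plot` colors points by participant (Okabe-Ito colorblind-safe
palette by default, cycled when N exceeds it) and draws each
participant's fitted line over that participant's observed covariate
range only — no extrapolation, no confidence bands on the lines.  The
optional overall line (gray, dashed) is the pooled OLS fit that treating
the rows as independent would give.  `comparison_panel` sets the rmcorr
plot between the pooled/per-occasion simple regression and the
averaged-per-participant regression.  All geometry is exposed through
`predicted_lines` and the matplotlib artists, so tests assert slopes and
counts on the data layer rather than on pixels.

## Testing and validation strategy

- Dual independent oracles for the estimator: Pearson on
  within-centered values, and a dummy-coded least-squares solve of the
  full design; 200 randomized unbalanced designs must agree to ≥ 10
  significant digits.  Cross-checks against statsmodels' ANCOVA table
  and pingouin's implementation guard against shared blind spots.
- Property-based tests (hypothesis, derandomized) for bounds, linear
  transformation invariance, per-participant shifts, measure-swap
  symmetry and generator determinism.
- Monte-Carlo calibrations, all seeded: type-I error of the F test,
  bootstrap coverage (500 datasets × 500 resamples at the default
  conditions), and analytic-vs-simulated power over a
  3 × 3 × 3 grid at 2000 simulations per cell.  Since per-cell
  deviations are approximately standard normal under exact calibration,
  the grid check allows the expected handful of ~2-SE excursions but
  none beyond 3 SE.
- Published worked examples pinned exactly where they are exact (the
  df values 32, 71, 9, 42) and with a stated ±0.015 band where only
  rounded inputs are available (the Fisher CIs).

Problem sizes in the default suite (hundreds of fits at L ≤ 1000, 500
bootstrap datasets, 54k power simulations) were chosen so the entire
suite runs in well under a minute on one core while keeping every
Monte-Carlo band meaningful.

## Known limitations

- The estimator assumes a common slope; it does not test slope
  homogeneity and no multilevel (varying-slope) alternative is fitted.
- No correction for attenuation due to measurement unreliability.
- Only the null rho_rm = 0 is testable; no general rho_0.
- Bootstrap intervals are percentile-only (no BCa), and with very few
  rows per participant within-cluster resampling is known to run
  slightly narrow.
- The analytic power path is exact for the Gaussian fixed-spread
  generative model; for real data it inherits the usual
  Pearson-machinery approximation.
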