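# Methods

## Estimand and design

A sharp RDD assigns treatment deterministically by thresholding a running
variable: d = 1 iff x ≥ x′ (ties are treated, matching an enrollment rule
of the form "score at or above the threshold enters the program").  Because
compliance is perfect, the jump in the conditional outcome mean at x′
identifies the Average Causal Effect for the subpopulation at the cutoff:

    ACE = δ = lim_{x↓x′} E(y|x) − lim_{x↑x′} E(y|x).

Three algebraically equivalent estimation routes are implemented:

1. **Two-sided**: fit y = α + β(x − x′) by OLS separately on each side of
   the cutoff (optionally inside a window of half-width h) and difference
   the intercepts, δ̂ = α̂_above − α̂_below.
2. **Pooled, "interaction"**: regress y on [1, x^c, d·x^c, d] with
   x^c = x − x′; β is the common slope, γ the treated-side slope offset.
3. **Pooled, "sidewise"** (default, the fuzzy model's form): regress y on
   [1, (1−d)x^c, d·x^c, d]; β and γ are the untreated and treated slopes
   directly.

Routes 2 and 3 are reparameterizations of the same four-dimensional model
space and route 1 spans it too, so fitted values, residuals and δ̂ coincide
to floating-point accuracy; the test suite asserts these identities against
an independent closed-form normal-equations solver.

## Fuzzy observations

An imprecise measurement is a triangular fuzzy number (lower, mode,
upper); a crisp value is the degenerate triple.  The estimation contract
is **defuzzify-then-OLS**: each triple is collapsed to a crisp value and
the crisp least-squares problem above is solved.  The default
defuzzifier is the centroid of the triangular membership function,
(lower + mode + upper)/3 — the minimal-assumption representative value
that (i) reduces exactly to the crisp value in the degenerate limit, so
the fuzzy estimator reproduces the crisp one bit-for-bit on crisp data,
and (ii) equals the mode for symmetric triples.  The mode is offered as an
alternative strategy so other readings of "imprecise observation" can be
compared; the strategy applies uniformly to y*, x* and the cutoff x′*
(which may itself be fuzzy).  General fuzzy arithmetic, α-cuts and
non-triangular membership families are out of scope; a fuzzy-error
decomposition of the residual is not attempted — the residual vector of
the defuzzified fit is reported as the model error e**.

Design-matrix note: writing the sidewise model in matrix form with
ψ = (α, β, γ, δ)ᵀ requires the four columns [1, (1−d)x^c, d·x^c, d]; adding
both an intercept and the pair {(1−d), d} would be exactly collinear, so
the four-column design is the unique full-rank matrix matching the model
term-by-term.

## Windows, ties and inference

* **Bandwidth h**: default unbounded (a global/parametric linear fit); a
  finite half-window is accepted as a user parameter.  No data-driven
  bandwidth selector is provided — with global linearity on each side the
  fit is parametric, and window choice is left to the analyst.
* **Ties**: x = x′ is treated everywhere — in the treatment indicator, the
  side-fit windows (below is (x′−h, x′), above is [x′, x′+h)) and the
  histogram binning — so no observation ever changes sides between
  components.
* **Standard errors**: classical homoskedastic OLS by default;
  cluster-robust errors (clustered on `cluster_id`, e.g. clinic) are an
  option, off by default since the model itself fits no cluster structure.
* At least 2 observations are required on each side of the cutoff inside
  the window; fewer raise `InsufficientDataError`, and a rank-deficient
  design (all in-window x identical) raises `SingularDesignError`.

## Density-discontinuity (manipulation) test

If subjects can nudge their score over the threshold, the running
variable's density jumps at the cutoff.  The test follows the standard
binned local-linear procedure:

1. **First stage**: histogram with half-open bins [edge, edge + b) aligned
   so the cutoff is a shared edge; normalised heights Y_j = count_j/(n·b).
   Default bin width b = 2·σ̂·n^(−1/2).
2. **Second stage**: local linear regression of Y_j on bin centers,
   separately below and above the cutoff, with triangular-kernel weights
   max(0, 1 − |X_j − x′|/h), evaluated at x′, giving f̂₋ and f̂₊.
3. **Statistic**: θ̂ = log f̂₊ − log f̂₋ with asymptotic standard error
   se = √((24/5)·(1/(n·h))·(1/f̂₊ + 1/f̂₋)); z = θ̂/se is referred to a
   standard normal, two-sided.

The default smoothing bandwidth follows the automatic rule of the binned
procedure: on each side a 4th-degree polynomial is fitted to the
normalised heights, and h_side = 3.348·[σ̃²·range / Σ_j f″(X_j)²]^(1/5)
with σ̃² the quartic fit's residual variance and the range the distance
from the cutoff to the data boundary; the final h is the mean of the two
sides, clipped to the side range when the curvature term degenerates (an
exactly-linear side has no curvature to trade off).  Both b and h are
plain parameters and can be overridden.  The test requires ≥ 10
observations per side and ≥ 2 populated bins inside each side's smoothing
window; a non-positive smoothed density raises `DegenerateDensityError`.

Monte Carlo calibration (asserted in the test suite): with n = 2000 draws
from a uniform density spanning the cutoff, the 5%-level rejection rate
over 500 repeats stays within 3 binomial standard errors of 5%; relocating
30% of the below-cutoff mass to just above the threshold yields p < 0.001
in ≥ 95% of repeats.

## Synthetic data generator

The generator emulates the screening-based study design; the reference
simulation design fixes only the cutoff (15) and the true parameters
ν = α + δ = 10, β = 0.5, γ = 0.3, so the remaining features are this
package's modelling choices, fixed once as defaults:

| parameter | default | units | why |
|---|---|---|---|
| x distribution | Normal(15, 5) truncated to [0, 40] | score | AUDIT-like 0–40 range centred on the cutoff so both sides stay populated |
| noise_sd | 1.0 | outcome | moderate residual noise relative to a jump of δ = 1 |
| (α, δ) split | α = 9, δ = 1 | outcome | any split with α + δ = ν targets the same ν̂; configurable |
| fuzz spreads | 0.5 on x and y | native units | mild imprecision, a small fraction of the running variable's SD |

One replication: draw n running values; fuzzify each into x\* (mode at the
true value, support endpoints shifted by spread·Uniform(0,1] on each side);
defuzzify to the *recorded* value; assign d from the recorded value, so the
treatment indicator always agrees with the assignment rule applied to the
data the estimator sees; evaluate the piecewise-linear mean
α + β(1−d)(x−x′) + γd(x−x′) + δd at the recorded value; add N(0, noise_sd²)
noise; fuzzify y.  Fuzzification of y perturbs its centroid by a mean-zero
amount, so estimation on centroids stays unbiased with slightly inflated
residual variance; fuzzification of x perturbs the regressor symmetrically
with variance spread²/54 (≈ 0.005 at the default spread), negligible
against the running variable's variance of ≈ 25.

What this generator does **not** emulate about real screening data:
discreteness of questionnaire scores (integer AUDIT values), heaping and
strategic answering (unless injected deliberately, as the density-test
examples do), cluster-level heterogeneity across clinics, loss to
follow-up, and any mismatch between the fitted piecewise-linear mean and
the true conditional mean.  Passing Monte Carlo checks therefore
demonstrates the estimator's correctness *under its own model*, not
robustness to misspecification.

## Monte Carlo harness

Replication r uses the generator seeded with
`SeedSequence(master_seed, spawn_key=(r,))` — the r-th spawned child — so a
single replication is reproducible in isolation and the full run is
reproducible from the master seed.  Each replication is fitted with the
fuzzy estimator (sidewise parameterization) and contributes
(ν̂, β̂, γ̂) = (α̂ + δ̂, β̂, γ̂).  Summaries report per-parameter mean,
bias, SD (n−1 divisor) and RMSE about the truth, which satisfy
rmse² = bias² + sd²·(reps−1)/reps exactly; normality of ν̂ is assessed by
the D'Agostino–Pearson omnibus test (needs ≥ 8 replications).  The
Monte-Carlo standard error used in the acceptance checks is sd/√reps.
Per-replication fit failures abort the run by default (`on_error="skip"`
drops them); a simulated dataset leaving a side with < 2 observations
fails by default (`side_policy="resample"` redraws, up to a cap).

Problem sizes: the shipped study uses 1000 replications at each
n ∈ {30, 50, 100, 200} — the reference design — which completes in well
under a minute; the dispersion of ν̂ falls monotonically with n
(consistency) and its distribution passes the omnibus normality test at
n = 200.

## Numerical choices and limitations

* OLS is solved through statsmodels (QR-based pseudoinverse); an explicit
  rank check raises `SingularDesignError` before fitting.  On ≤ 10-point
  instances coefficients agree with the closed-form normal-equations
  solution to 1e-10 relative tolerance.
* Text serialisation uses `%.17g` floats and round-trip parsing, so
  datasets and fit reports survive write-then-read bit-for-bit.
* Fit reports are written atomically (temp file + rename): a failed run
  leaves no partial output.
* The estimator targets the effect *at the cutoff* only; no covariate
  adjustment, kernel weighting, higher-order local polynomials or
  robust bias-corrected inference are provided.  Imperfect-compliance
  (fuzzy-RDD) designs are out of scope — with sharp assignment there are
  no noncompliers.
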