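# Methods

## The model

`sitar` fits a shape-invariant mixed-effects growth model to a set of
growth curves.  The intended data are *survey means*: national
anthropometric surveys tabulated as mean height (cm) or weight (kg) by
1-year age group, sex, country and year of measurement, with each survey's
mean curve treated as one "individual".  On the fitting scales the
prediction for survey *i* at (transformed) age *t* is

    y_it = a0 + alpha_i + h( exp(c0 + gamma_i) * (t - b0 - beta_i) ) + e_it

where

* `h` is a natural cubic B-spline (linear beyond its boundary knots) shared
  by all curves, with `df` free coefficients and `df - 2` interior knots at
  the equally spaced `k/(df-1)` quantiles of the fitting-scale ages
  (type-7/linear-interpolation quantiles);
* `alpha_i` (**size**, cm or kg), `beta_i` (**timing**, years) and
  `gamma_i` (**log-intensity**) are zero-mean survey-level random effects
  with an unstructured 3x3 covariance, accompanied by the fixed effects
  `(a0, b0, c0)`;
* `e_it` is independent Gaussian residual error with SD `sigma` on the
  fitting scale (optionally inverse-variance weighted by the per-cell
  sample size `n`; unweighted by default, since survey cells of 10^3-10^4
  children make the weights immaterial).

Intensity is reported as `100 * gamma_i` percent: +4% means the survey
passes through the growth period 4% faster than the mean curve (its age
axis is compressed by `exp(gamma) ≈ 1.04`).  Curves mapped through the
inverse transformations superimpose on the mean curve when the model fits;
the residual scatter of the superimposed points equals `sigma`.

Applied to a secular-trend series, size measures the change in adult
stature after adjusting for maturation, timing the advance of the pubertal
spurt, and intensity the shrinkage of the growth period.

### Identifiability conventions

The natural-spline space contains constants, which would alias the size
intercept.  The basis is therefore split internally into the constant
direction and its orthogonal complement (df - 1 columns); `a0` carries the
constant.  The free parameter count per fit is `(df - 1)` spline
coefficients + 3 fixed effects + 6 covariance entries + 1 residual SD,
and this count enters the BIC penalty.

`b0` and `c0` are aliased with reshaping the free spline up to the
discreteness of the knots, which makes the joint likelihood nearly flat
along that direction; see *Numerical choices*.  The random-effect means are
absorbed into the fixed effects iteratively during fitting and the reported
effects are exactly centered.

## Estimation

The marginal likelihood integrates the three random effects per survey.  It
is approximated by Laplace's method:

* **inner problem** — for each survey, a damped Newton iteration with
  analytic gradients and full analytic curvature (first and second basis
  derivatives) finds the posterior mode of `(alpha, beta, gamma)`; the
  surveys are solved batched.
* **determinant** — the Laplace determinant uses the Gauss-Newton
  (expected-information) form `J'WJ/sigma^2 + Omega^{-1}` of the mode
  curvature.  It is positive definite by construction, which keeps the
  approximate likelihood bounded even at iterates where the exact
  observed-information form would be indefinite; at a converged mode with
  small residuals the two differ negligibly (the package's tests bound the
  gap to adaptive Gauss-Hermite quadrature by 0.05 log-units on small
  instances).
* **outer problem** — L-BFGS-B over spline coefficients, fixed effects, the
  Cholesky factor of the random-effect covariance (log-diagonal
  parameterization) and log residual SD, with finite-difference gradients
  on rescaled parameters.  The inner warm start is held fixed within each
  outer iteration and refreshed only at accepted iterates, so the objective
  the optimizer sees is a consistent function of the parameters.

Maximum likelihood (not REML) is used so BIC comparisons across `df` and
fixed-effect structures are coherent; `n` in the BIC penalty is the total
observation count.  Fitting is deterministic — no random number enters the
optimizer; all seeds live in the synthetic-data generator.

### Starting values

Spline coefficients and `a0` from a pooled least-squares fit; `b0` at the
age of the maximum pooled-curve derivative; `c0 = 0`; random effects 0;
covariance `diag(1 cm^2, 0.25 yr^2, 0.01)` mapped through the transform
Jacobians when fitting on transformed scales; `sigma` from the pooled
residuals.

### Numerical choices

* Convergence: relative objective change below `1e-8` or projected-gradient
  sup-norm below `1e-5` (on rescaled parameters), `max_iter` 2000 outer
  iterations (finite-difference quasi-Newton steps are cheap and some
  transformed-scale fits need over 500); exceeding `max_iter` raises.  A line-search stall at the
  finite-difference noise floor is treated as converged.
* The spline argument is anchored by centering transformed ages and placing
  knots on the starting-value scale, so the basis support tracks the data.
* Inner Newton: Levenberg-style damping with per-survey Armijo
  backtracking; tolerance `1e-9` relative on the gradient; a survey that
  repeatedly fails to improve is accepted at its numerical optimum.
* Variance floors: random-effect SDs are bounded a factor `e^6` below their
  starting values and the residual SD a factor `e^5` below its start.  A
  variance at its floor is a boundary (zero-variance) fit and is flagged
  with a warning, not an error — expected when curves are near-identical.
* The log age-scale factor is clipped at |c| = 8 inside the residual
  evaluation to prevent overflow during wild line-search trials.
* `select_df` breaks BIC ties toward smaller `df` (parsimony).
* Degenerate inputs: a single survey raises (random effects unidentifiable);
  empty tables and curves with under 4 distinct ages are rejected at
  validation.

## Axis transformations

Age and size may each be fitted on the identity, square-root or log scale.
Effects are absolute on identity scales and proportional on log scales;
the square root is intermediate.  Fitted curves, effects and velocities
are reported back in natural units:

* size effects on transformed scales are back-converted at the mean
  curve's adult (oldest-age) level, matching the convention of quoting the
  adult-size impact in cm or kg;
* timing on transformed age scales is the difference between the survey's
  and the mean curve's age at peak velocity (a horizontal shift on a
  transformed axis is age-varying in natural years, so it is measured where
  timing is defined — at the spurt);
* velocity is the exact chain-rule derivative through both transforms, so
  its trapezoid integral reproduces the distance increment (tested at 1e-3
  relative).

Log-likelihoods on different size scales refer to different response
variables; the scan adds the log-Jacobian `sum log|dg(y)/dy|` of the size
transform before comparing across strata, and also reports the per-stratum
(no-correction-needed) rankings.  Whether knots are placed on the
transformed or natural age scale is not externally determined; this
implementation places them on the transformed (fitting) scale, the scale on
which the spline is estimated.

## Period and cohort curves

A *period* table slices the data by measurement year; a *cohort* table
follows one birth year, taking age group `a` from measurement year
`b + a` (age group `a` covers completed years `[a, a+1)`, mean age
`a + 0.5`).  The period curve of year `y` pairs with the cohort born
`y - 11`, which has mean age 11.0 — the midpoint of the 1-20 range — in
mid-year `y`.  Cohorts at the edges of the measurement span are kept as
partial curves; the fit tolerates unbalanced curves.  Annual series can be
merged into 3-year groups centred on decade years (n-weighted when counts
are available) to reduce sampling noise, mirroring how annual national
surveys are summarized.

When a monotone secular trend is injected by measurement year, the
period-fitted intensity range exceeds the cohort-fitted one whenever the
trend bends (fast-then-plateau): within each cohort curve the later ages
carry later-period effects, and the cohort-specific part of that
within-curve gradient leaks into the curve's own intensity estimate with
opposite sign on the steep flank.  Under an exactly linear trend the
within-curve gradient is common to all curves and is absorbed by the mean
curve, so the two ranges agree.

## The synthetic-data generator

`synthetic_data` inverts the model: a fixed template curve plus per-survey
`(alpha, beta, gamma)` plus independent Gaussian noise per age-group mean.
Defaults are the study conditions used throughout the tests: 12 surveys
(7 decennial Japan-style 1950-2010, 5 Korea-style 1965-2005) x 19 mid-year
ages 1.5-19.5, noise SD 0.3 cm / 0.3 kg.  The upper age group is taken as
completed year 19 (midpoint 19.5); the tabulation convention is ambiguous
about whether a 20th group exists, and either choice only moves the "adult"
anchor by one year.  The default effect schedules encode the reported
secular-trend magnitudes for the two countries — height size changes of
about 8 cm (Japan-style, mostly before 1980) and 5 cm (Korea-style, mostly
after 1984), an overall intensity range of 15%, timing flat in Japan after
1970, and for weight a 2.5-year Korea-style timing advance with boys
changing roughly twice as much as girls.

Templates are parametric presets with frozen constants (documented in the
module): a Preece-Baines-type curve for height (≈75 cm at age 1.5 rising to
≈172/158 cm with a spurt near 13/11 years by sex) and a linear-plus-logistic
curve for weight (≈10 kg rising to ≈62/52 kg).  They are synthetic
stand-ins shaped like East-Asian national survey means, not published
reference curves.  A template may be declared on transformed axes
(`Template.on_scales`), in which case the effects act on those scales —
this is what makes scale-selection experiments honest, because the
generating scale is then a recoverable ground truth.

Noise is independent across age cells (survey means of very large samples
have negligible shared error; no within-curve autocorrelation is
simulated).  The generator works on its declared scales regardless of the
scales later used for fitting.

### What the generator does and does not emulate

It reproduces the data *structure* (survey-mean curves, effect magnitudes,
noise level) but generates an *exactly* shape-invariant world.  Real survey
curves deviate from exact shape invariance, which is why published
variance-explained figures sit near 97% while fits to these synthetic
tables reach ~99.5%.  Likewise the age profile of real secular increments
(a 5 cm infant increment against an 8-10 cm adult increment under an
advancing-timing trend) reflects curve-shape change that an identity-scale
shape-invariant truth cannot produce; increment outputs on synthetic data
test internal consistency (observed vs model-predicted, antisymmetry, the
velocity-integral identity), not those published magnitudes.  Passing tests
therefore demonstrate correctness of the estimation machinery under the
model, not goodness of the model for any particular real dataset.

## Problem sizes

The canonical fit — 12 curves x 19 ages, df 6 — takes seconds.  The
recovery study uses 20 seeded replicates of the default generator; the
scale contrast fits identity-age against sqrt-age models at df 6 on a
five-survey sqrt-age-truth scenario; the
period/cohort comparison simulates 63 annual surveys (1949-2011), merges
seven decennial triennia and fits seven period and seven cohort curves.
These sizes keep every analysis stage exercised end-to-end while the whole
suite stays lightweight.

## Known limitations

* Individual-child longitudinal data, covariates, centiles, REML and
  bootstrap uncertainty are out of scope.
* The Laplace approximation is excellent at survey-mean noise levels but
  untested here for large residual noise with few observations per curve.
* With only 2 curves the random-effect covariance is always degenerate and
  the fit lands on a boundary; estimates are returned with a warning but
  should be read as descriptive only.
* BIC comparability across size transforms relies on the standard
  change-of-variables correction; rankings *within* a size transform need
  no correction and are also reported.
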