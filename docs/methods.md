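# Methods

## Model

`dcsm` implements dual change score models (DCSMs): latent growth models
in which the change of a trait's latent true score between adjacent age
bins has a constant part and parts proportional to the previous state of
the system.  Time is chronological age discretized into half-open bins
(default 2-year bins covering ages 50 to <90, so bin t spans
[50+2t, 52+2t) and the intercept is defined at exact age 50, the lower
edge of bin 0).  For the bivariate case with traits y (frailty index,
percent) and x (an epigenetic clock), the latent dynamics are

    y[0] = I_y                                  x[0] = I_x
    Δy[t] = α·S_y + β_y·y[t-1] + γ_{x→y}·x[t-1]
    Δx[t] = α·S_x + β_x·x[t-1] + γ_{y→x}·y[t-1]

with α fixed to 1 by convention (it only scales the slope factor).  β is
the proportional (self-feedback) coefficient that produces accelerating
or decelerating curves; γ are the cross-trait couplings that encode
lead–lag structure: γ_{x→y} ≠ 0 means the clock's previous level
predicts the subsequent *change* in frailty over and above the static
factor correlations.

Because the recursion is linear in the growth factors
f = (I_y, S_y, I_x, S_x), the latent trajectory is L(β, γ)·f for a
loading matrix built by running the recursion on basis vectors; the
observed data are therefore multivariate normal and the whole model
reduces to structured mean and covariance functions.

Growth factors live at two levels.  Individual factors are
N(0, Σ_ind); twin-pair factors are N(0, Σ_pair) and shared by co-twins,
which induces cross-twin covariance L Σ_pair Lᵀ without committing to a
genetic (MZ/DZ) decomposition — zygosity is carried as metadata only.
Σ_pair may be restricted to a subset of factors ("intercepts_only", or
an explicit list such as keeping both frailty factors plus only the
clock intercept, the reduced structure used for pace-of-aging models
when the full one will not converge).  Sex (0 = man, 1 = woman) shifts
the factor *means* only, so a sex effect on an intercept propagates
through the dynamics rather than translating the curve rigidly.
Occasion residuals are independent across bins and twins, with constant
per-trait variance and an optional within-person, within-bin cross-trait
covariance.

## Estimation

The objective is full-information maximum likelihood: each twin pair
contributes the normal log-density of exactly its observed entries under
the corresponding sub-mean and sub-covariance of the stacked pair vector
(2 twins × traits × bins).  Singletons are pairs whose co-twin is
entirely missing; persons with no observations contribute nothing.
Pairs are grouped by missingness-pattern size so the sub-moments can be
gathered and Cholesky-factorized in batches; because sex enters only the
mean, one implied covariance serves every pair per parameter value.

Free parameters are optimized on an unconstrained working scale:
covariance blocks through lower-triangular square roots (every iterate
is positive semi-definite by construction), residual variances through
logs, everything else directly.  The gradient is computed analytically —
the standard MVN results dℓ/dμ = Σ⁻¹r and dℓ/dΣ = (Σ⁻¹rrᵀΣ⁻¹ − Σ⁻¹)/2
per pattern, scattered into the pair layout and chained through the
loading recursion (forward-mode derivative recursions for β and γ) and
the square-root/log transforms — and is verified against finite
differences in the test suite.  Maximization uses L-BFGS-B
(ftol 1e-10, gtol 1e-5); non-convergence is reported in the result,
never raised.  Standard errors come from the observed information
(finite differences of the analytic gradient at the optimum), mapped to
the natural scale — covariance entries rather than square-root factors —
by the delta method; when the information matrix is not positive
definite the SEs are flagged unavailable.

Default starting values are data-driven: first-bin trait means for the
intercepts (pooled OLS intercept as fallback), mean per-person
least-squares slopes, zero dynamics and sex effects, and diagonal
covariances scaled to the observed trait variance (0.4/0.01 of it for
individual intercept/slope variance, 0.1/0.0025 at pair level, 0.3 for
the residual).  Nested fits are warm-started from the parent model's
optimum (and vice versa when a nested fit beats its parent), which
enforces the log-likelihood monotonicity that likelihood ratio tests
assume.

Model comparison is the classical chi-square LRT.  The univariate
ladder tests the proportional term (β kept iff p < .05).  The bivariate
ladder fits four coupling structures on top of the retained univariate
structure — bidirectional, none, and the two unidirectional models —
accepting no-coupling if it is not significantly worse than
bidirectional, otherwise whichever unidirectional survives; if both
survive, the tie is reported rather than silently broken.  For variance
components on the PSD boundary the naive chi-square reference is
conservative; boundary-corrected mixture references are out of scope.

## Synthetic cohort

The generator emulates the design of a Swedish twin study of aging
(SATSA-like): 524 individuals, same-sex twin pairs, 58.6% women, one to
six visits per person with probabilities 157/123/113/89/41/1 out of 524,
visit spacing uniform on 3–6 years, zygosity metadata 34.5% MZ / 65.3%
DZ / 0.2% unknown.  Quantities the cohort description does not pin down
are fixed once as plausible choices and documented here: entry age
uniform on [50, 84] (reproducing a mean entry age near 68), and a 60%
share of individuals with a participating co-twin (the singleton share
is not reported for the analyzed subsample).  Scheduled visits past the
grid's upper edge are dropped at binning, exactly as the data pipeline
drops sparse very-old ages, so the default design schedules ≈1 309
visits of which ≈1 190 usable person-bins survive.

Simulation runs the model generatively: shared pair factors, individual
factors, sex effects on factor means, the latent recursion, then
occasion residuals at the scheduled visits only.  Trait values are
continuous and unbounded, as the Gaussian model assumes; clipping the
frailty index to [0, 100] is available only as a stress-test flag.  The
simulator deliberately omits features of real cohorts: attrition is
independent of the traits (informative drop-out is a known limitation of
the emulated design), deficits are not simulated at the item level, no
MZ/DZ difference in sharing, and clock values appear directly rather
than being derived from methylation arrays.  Passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions, not robustness to their violation.

`recovery_experiment` repeatedly simulates and refits, reporting
per-parameter mean estimate, bias, empirical SD, Monte-Carlo SE, mean
reported SE and 95% Wald coverage; replicates that fail to converge are
counted and excluded.  Fits start at the generating values, the usual
simulation-study convention (data-driven starts are exercised
separately).

## Reference parameter sets

`dcsm.presets` bundles best-fitting bivariate estimates for the frailty
index paired with each of five DNA-methylation clocks (PC-corrected
age-trained clocks PCHorvathAge/PCHannumAge, condition-trained
PCPhenoAge/PCGrimAge, and the pace-of-aging clock DunedinPACE on a ×10
scale).  The four age/condition clocks use no coupling; the pace clock
uses a clock→FI coupling of 1.19 and the reduced pair-level structure.
Printed to two decimals, a few covariance blocks are slightly indefinite
(e.g. a slope variance printed 0.00 beside nonzero covariances); each
block is projected to the nearest PSD matrix by clipping negative
eigenvalues, and the pace clock's individual-level slope variance —
printed as 0.00 but flagged significant — is set to 0.004, consistent
with the rounding.  Projection leaves means, slopes, β and γ untouched.
A side effect worth knowing: the pace-preset pair-level covariance is
exactly singular after projection, so simulate-and-refit experiments at
that truth show genuine boundary bias in pair-level variance estimates
(the estimator cannot undershoot a zero eigenvalue).

## Numerical choices and edge cases

* PSD validation clips eigenvalues in (−1e-10·scale, 0); harder
  violations raise instead of silently repairing.
* Half-open bins: a boundary age belongs to the bin it starts; ages at
  or past the upper edge are unassignable and dropped with a logged
  count.  Two visits in one bin keep the chronologically first, with a
  warning.
* The frailty index divides by the number of *available* items; it is
  undefined (an error) with zero available items.
* LRT statistics that come out negative (possible only when the full
  fit is at a worse optimum) are floored at zero with a warning after
  the warm-start exchange.
* On very short grids (about 3 bins) with sparse per-person visits the
  unrestricted FIML likelihood is unbounded — singular-covariance spikes
  can interpolate low-dimensional patterns exactly.  This is a property
  of the model class; fitting should use grids long enough that observed
  patterns exceed the latent rank (the default 20-bin grid is safe).

## Problem sizes used by the test suite and acceptance script

Chosen as the package's own balance of statistical resolution and
runtime on a single core: recovery experiments use the full 524-person
design with 10–12 replicates; selection calibration uses 20 replicates
for the univariate type-I check and 8 for the bivariate no-coupling
retention check, judged against exact 99.9% binomial bands around the
nominal rates; moment consistency uses 100 000 complete pairs on a
3-bin bivariate model (a 12-dimensional layout keeps the 3-SE
every-entry criterion meaningful).  Calibration replicates start their
fits at the generating values (admissible for every coupling variant
when the true couplings are zero) and relax the objective tolerance to
1e-9 — likelihood-ratio statistics only need ~1e-2 resolution, and the
warm-start exchange between nested and full fits keeps them
conservative.

## Known limitations

* Naive chi-square reference for boundary variance components.
* No sex-stratified variances (sex enters means only), no continuous-
  time dynamics, at most two coupled traits, equal bin widths.
* Standard errors assume an interior optimum; near the PSD boundary the
  observed information can be ill-conditioned and SEs are then flagged
  rather than fabricated.
* Real-data baseline correlations and fitted estimates of the emulated
  cohort are not reproduced here; the package's evidence is oracle
  equivalence and simulation-based recovery.
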