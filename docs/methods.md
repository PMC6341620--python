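# Methods

## Model and estimators

The package treats the simple (single-mediator, no-interaction) mediation
model with a binary outcome Y, continuous exposure X and a mediator M that is
either continuous or binary. Three equations are fitted per dataset:

1. `logit P(Y=1) = i1 + c X`
2. `M = i2 + a X` — ordinary least squares when M is continuous,
   logistic maximum likelihood when M is binary
3. `logit P(Y=1) = i3 + c' X + b M`

Logistic fits use Newton iterations (gradient tolerance 1e-8, at most 100
iterations, delegated to statsmodels). A fit whose coefficients exceed 15 in
absolute value is treated as complete or quasi-complete separation and raises
rather than returning divergent numbers; non-convergence likewise raises.
Sample variances and covariances use denominator n−1, the mediator-equation
residual variance n−2. These conventions matter only at third-decimal level
for n = 1000 but are fixed for reproducibility.

### Scale problem and standardizations

A logistic coefficient is the effect on a latent continuous outcome whose
error SD is fixed at sqrt(π²/3) ≈ 1.8138. Adding a mediator that predicts Y
inflates the latent outcome's total variance, hence the scale of every
coefficient in equation 3 relative to equation 1. The package implements the
three standard remedies:

* **y-standardization** divides each coefficient by the latent SD of its
  equation's dependent variable: `SD(Y1) = sqrt(c² VAR(X) + π²/3)`,
  `SD(M2) = sqrt(a² VAR(X) + π²/3)` (binary M only; a continuous M's linear
  equation needs no rescaling), and
  `SD(Y3) = sqrt(c'² VAR(X) + b² VAR(M) + 2 b c' COV(X,M) + π²/3)`.
* **full-standardization** additionally multiplies each coefficient by the
  sample SD of its own independent variable (X for c, a and c'; observed M
  for b). For the a path the dependent-variable scale is the observed SD of
  M when M is continuous (linear equation) and the latent `SD(M2)` when M is
  binary (logistic equation). This choice — observed SD as the independent-
  variable scale of b, latent SD as the dependent-variable scale of a —
  makes the binary-mediator full-standardized product equal the
  y-standardized product times SD(M), which is the internally consistent
  reading; see Limitations for the one published value it cannot reproduce.
* **standardized logistic solution** rescales c onto the metric of c' via
  `c_std = c sqrt(1 + b² σ²_MX / (π²/3))` with σ²_MX the mediator-equation
  residual variance — defined only for a continuous mediator.

π²/3 is carried at full double precision throughout.

Per-sample standardization uses each sample's own fitted coefficients and
sample moments; true values use the true coefficients and population moments.

### Potential-outcomes (natural) effects

Under no unmeasured confounding and no exposure–mediator interaction, the
natural indirect effect for a binary mediator has the odds-ratio form
`(1+e^{i2})(1+e^{b+i2+a}) / [(1+e^{i2+a})(1+e^{b+i2})]`; the package
evaluates its log via `logaddexp` so extreme coefficients cannot overflow.
The natural direct effect log-OR is c', and the total effect is defined as
their sum on the log scale — which makes the three proportion-mediated
formulas coincide for this method, so a single value is effectively
reported. For a continuous mediator the natural indirect effect reduces
algebraically to `a·b` and the implementation reuses the identical arithmetic
(the equality is bit-for-bit, and tested as such).

The difference estimator `c − c'` is reported for the crude and standardized
rows but not for the potential-outcomes row, where total = direct + indirect
by definition makes it redundant.

Proportions mediated outside [0, 1] (inconsistent mediation) are reported
as-is and flagged, never clipped. A proportion whose denominator is
numerically zero (|denom| < 1e-12) is recorded as undefined rather than
propagated as NaN; the simulation harness excludes such replicates from that
estimator only and counts them.

## Truth engine

Each simulated condition fixes a = b = c' = 0.6, X ~ N(0, 1), and target
marginal prevalences in {0.1, 0.3, 0.5} for the binary variables. The
generating intercepts are solved from the marginal-prevalence equation
`E[expit(i + η)] = target` with the expectation taken by 96-node
Gauss–Hermite quadrature over the normal exposure (and, for a binary
mediator, the two-point mediator distribution inside it), and the root found
by Brent's method to 1e-12. For symmetric cases this reproduces the exact
answers (i2 = 0 at mediator prevalence 0.5; i3 = −b/2 at binary-M 0.5/0.5).

Population moments follow in closed form for a continuous mediator
(`VAR(M) = a² VAR(X) + σ²`, `COV(X,M) = a VAR(X)`) and by quadrature for a
binary one (`VAR(M) = p̄(1−p̄)`, `COV(X,M) = E[X expit(i2+aX)]`); the binary
covariance is cross-checked in the tests against a Stein-identity form and a
10⁷-draw Monte-Carlo estimate.

True estimator values are obtained by applying each standardization to the
true coefficients and population moments. Two conventions deserve note, both
the package's own decisions where the generating recipe is ambiguous:

* "Continuous mediator with mean 0 and variance 1" is read as unit
  *residual* variance (marginal variance 1.36). This is the reading
  consistent with the published y-standardized true value (0.168; the
  unit-marginal reading gives 0.171).
* The outcome is generated structurally from equation 3; the marginal c of
  equation 1 is a derived quantity, and all crude estimators (product and
  difference alike) are scored against the single structural truth
  a·b = 0.36. The standardized-logistic row is likewise scored against 0.36,
  which is the value its rescaling is designed to recover. The true
  proportion mediated for every regression-based row is the structural
  `ab/(ab+c') = 0.375`; the potential-outcomes row is scored against its own
  `ie/(ie + c')`.

## Monte-Carlo harness

Replicates draw X, then M, then Y in a fixed order from a
`numpy.random.Generator` seeded by (master seed, CRC-32 of the condition
label, replicate index) through `SeedSequence` — so any subset of conditions
or replicates is bit-reproducible and results are independent of execution
order or parallel scheduling. Bias is the mean deviation of replicate
estimates from the estimator's own truth, MSE the mean squared deviation.
Replicates whose fit fails (separation, non-convergence) are excluded with a
count; a condition aborts if more than 1% fail (at these effect sizes and
n = 1000 failures essentially never occur).

The default study scale is the full one — 500 replicates of n = 1000 per
condition, about 3 s per condition — and the acceptance tests run two
headline conditions (continuous mediator at outcome prevalence 0.5; binary
mediator at 0.5/0.5) at that full scale. Monte-Carlo comparisons against the
published bias values use a tolerance of `max(0.01, 3·sqrt(MSE/500))` with
the published MSE — three Monte-Carlo standard errors of an independent
replication, since the original study's random-number machinery is unknowable.

## What the generator does and does not emulate

The synthetic-data generator reproduces the study conditions exactly as
specified: marginal-normal exposure, logistic (or linear-normal) mediator,
logistic outcome, no confounding, no exposure–mediator interaction, no
missing data. Real cohorts violate most of these: confounders, measurement
error, non-normal exposures, interactions. Passing tests therefore
demonstrate correctness of the estimators and of the harness under the
stated generating model, not robustness of any estimator in observational
practice. The published cohort application (n = 360) has no deposited data;
the `analyze` workflow is instead validated end-to-end on generated fixtures
whose truth is recorded in a JSON sidecar.

## Known limitations

* The published full-standardization true value for a continuous mediator
  (0.196) is not reproducible under any reading of the stated procedure we
  could construct — every natural reading yields the y-standardized value
  0.168 when VAR(X) = 1, which is what the package computes. The same holds
  for the binary-mediator prevalence-0.1 entry (published 0.048; the
  procedure gives 0.029, breaking the otherwise consistent pattern of the
  0.3 and 0.5 columns). The implementation follows the stated procedure and
  documents the discrepancy rather than reverse-engineering the printed
  numbers.
* The potential-outcomes true indirect effect at mediator prevalence 0.1
  depends on the (unstated) intercept convention at the third decimal; the
  quadrature convention used here gives 0.0461 against a published 0.047.
* Confounder adjustment, exposure–mediator interaction, confidence intervals
  and significance tests for the indirect effect, and alternative outcome
  models (linear probability, log-linear, marginal effects) are out of scope.
* SEM is not implemented as separate machinery: fitting the equations
  jointly or separately is mathematically equivalent here, so one fitter
  serves both labels.
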