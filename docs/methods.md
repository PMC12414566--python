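# Methods

This note documents the statistical models, algorithms, numerical
choices and known limitations of `growthmix`.

## Model family

A latent growth model for an outcome measured at scheduled visits
`t_1 < … < t_T` assumes `K` latent classes with mixing proportions
`π` on the simplex.  Within class `k` the observation vector of
subject `i` is multivariate normal over that subject's observed visits,

```
y_i | class k  ~  N( X_i β_k ,  Z_i Ψ_k Z_i' + Θ_k )
```

where `X_i` is the polynomial design (order 1–3, class-specific),
`Z_i` the random-effect design (columns for intercept and/or linear
slope), `Ψ_k` the random-effect covariance (absent for GBTM/LCGA,
shared for class-invariant GMM, per class for class-variant GMM) and
`Θ_k` a diagonal residual matrix whose variances are a single scalar,
per-visit, per-class, or per-class-per-visit.  Random effects enter
only through this marginal covariance — the linear-Gaussian structure
makes the integral exact, so no numerical integration is ever
performed.  Under missing-at-random data each subject contributes the
density restricted to observed visits (FIML); the marginal
log-likelihood is `Σ_i log Σ_k π_k φ_k(y_i^obs)`.

Parameter counting follows directly: `Σ_k (order_k + 1)` fixed
effects, `r(r+1)/2` covariance terms once or per class, 1/T/K/K·T
residual variances, and `K − 1` proportions.

## Estimation

**EM with closed-form M-steps.**  Treating both the class label and
the random effects as missing data gives a closed-form M-step:
proportions from mean posteriors; per-class weighted least squares for
`β_k` on `y_i − Z_i E[b_i]`; `Ψ` from the posterior-weighted second
moments `E[b]E[b]' + Cov(b)`; residual variances from weighted squared
residuals plus the trace correction `z_t' Cov(b) z_t`, pooled
according to the residual structure.  The conditional-maximization
sequence is monotone in the marginal log-likelihood.

**Woodbury computations.**  Because `Θ` is diagonal, all per-subject
quantities reduce to batched `r × r` (r ≤ 2) linear algebra via the
push-through identity
`Σ⁻¹ = Θ⁻¹ − Θ⁻¹Z (I + ΨS)⁻¹ Ψ Z'Θ⁻¹` with `S = Z'Θ⁻¹Z`, and
`log|Σ| = Σ_obs log θ + log det(I + ΨS)`.  No per-missingness-pattern
loops are needed; an independent dense-covariance implementation of
the same likelihood (used by `marginal_loglik`) serves as a
cross-check in the test suite.

**Acceleration and convergence.**  Plain EM converges slowly near the
optimum, so EM steps are interleaved with SQUAREM (squared secant)
extrapolation; an extrapolated step is accepted only when it does not
lower the likelihood, preserving monotonicity.  Default convergence is
a relative log-likelihood change below 1e-8 with a 2000-iteration cap,
followed by an optional L-BFGS polish of the full likelihood in an
unconstrained parameterization (softmax proportions, Cholesky factors
for `Ψ`, log variances).  Residual variances are floored at
`1e-6 · var(y)` to prevent likelihood singularities; an active floor
is flagged in the convergence report.

**Multistart protocol.**  Starting values come from a perturbed
nearest-centre partition of subject-level intercept/slope estimates;
`β` is initialized by pooled within-partition least squares, `Ψ` by a
method-of-moments projection of class-residuals onto the random-effect
design with the least-squares sampling noise subtracted.  A two-stage
scheme runs all starts for a few iterations and the best quarter to
convergence (the study protocol: 500 and 500/4 starts); the
replication rule fits twice with independent seeds and doubles the
number of starts until the best log-likelihoods of two runs agree
within tolerance (default 1e-4).  Time is rescaled to the unit
interval internally for conditioning and coefficients back-transformed
to month units.  All randomness descends from a single seed; a fit is
bit-reproducible.

Standard errors for growth coefficients are expected-information GLS
standard errors, `inv(Σ_i ŵ_ik X'V_k⁻¹X)`, conditioning on the
estimated classification; they feed the Wald pruning step and are not
intended as final-inference standard errors.

## Model selection

The four-stage ladder fits increasingly less constrained models:
(1) a single-class growth curve baseline; (2) GBTM class enumeration
K = 1…6; (3) residual relaxation over time, classes, or both (LCGA);
(4) class-invariant then class-variant random intercepts and slopes.
Admissibility is the hard 5% minimum class share plus a significant
bootstrap LRT for K vs K−1; scaled entropy (> 0.5) and APPA (> 0.7)
floors are advisory by default (reported in the audit, enforceable via
`floors_hard`) because published solutions themselves sit at or below
the entropy floor.  Within a 2-point BIC margin the more parsimonious
model wins.

Two desk-scale implementation choices:

* **Lazy LRT.** The bootstrap LRT is evaluated only for the
  BIC-preferred K, walking down while non-significant, rather than for
  every enumeration step — identical decisions at a fraction of the
  bootstrap cost.
* **Class-count reassessment.** Enumeration happens under the most
  constrained (GBTM) model, where unmodeled residual heterogeneity or
  random effects can masquerade as extra classes — a well-documented
  over-extraction mechanism.  With `reassess_k` (default on), the
  relaxed-residual stage also fits K−1 and the class count is
  re-decided by BIC under the better-specified within-class model;
  stage 4's winner is confirmed against K−1 the same way.

The likelihood ratio test is a parametric bootstrap: `replicates`
datasets are simulated from the fitted (K−1)-class model (complete
data re-masked with the observed missingness), both models are
refitted with a deliberately light protocol, and
`p = (1 + #{boot ≥ observed}) / (R + 1)`.  The published "adjusted
LMR bootstrap LRT" phrase conflates two distinct tests; the bootstrap
version is implemented as the operative test (self-contained, no
asymptotic adjustment), with the naive −2ΔLL reported alongside.
Because the observed and bootstrap fits can share the same light
protocol, the test remains calibrated even with truncated
optimization, which the acceptance suite verifies empirically.

Polynomial refinement drops, per iteration, the highest-order
non-significant coefficient (two-sided Wald at α = 0.05 by default,
largest p first) and refits with labels realigned by Hungarian
matching on the modal cross-tabulation.  Candidate fits during stages
3–5 are single screening fits warm-started from the previous stage's
solution (mapped across structures by `adapt_parameters`); the final
selected model is re-estimated under the full replicated protocol.

Within-class normality uses Mardia's multivariate skewness
(`n b₁/6 ~ χ²`) and kurtosis (normal approximation) statistics on
complete-case subjects per modal class; classes smaller than
`max(floor, T + 2)` are marked not assessable.  Hand-coded because the
installed statistics libraries provide other multivariate normality
tests (e.g. Henze–Zirkler), not Mardia's.

## Manual 3-step covariate analysis

Step 2 extracts the misclassification matrix
`P(modal s | true k) = Σ_{i: modal=s} p_ik / Σ_i p_ik` and its logit
parameterization (capped at ±30 where probabilities vanish).  Step 3
models membership on one covariate at a time by maximum likelihood
with the measurement part fixed at those logits; odds ratios are
exponentiated multinomial-logit coefficients against a configurable
reference class, with Wald intervals from a finite-difference Hessian.
Covariates are standardized internally and back-transformed; a log
transform is available for skewed covariates.  Complete separation is
flagged and the interval reported unbounded.

**What "class distribution unchanged" means.**  With the measurement
model fixed, the modal classification entering step 3 is data and
cannot change — the class distribution (modal counts) is invariant by
construction, and the intercept-only structural proportions are
exactly stationary at the unconditional estimate (provable from the
score equations; tested to 1e-6).  The *estimated structural*
proportions of a model that includes a covariate can move at sampling
order O(1/N); this is a property of the ML 3-step itself, not of the
implementation.

Distal outcomes are added with class-specific means (continuous,
common variance) or log-odds (binary) under the same fixed logits;
pairwise Wald chi-square tests compare classes, standardized mean
differences divide by the sample standard deviation, and boundary
(empty-cell) maxima are detected by probing the capped log-odds,
reported as unbounded odds ratios.  Cross-trajectory risk ratios use
the modal cross-tabulation (posterior-weighted mode available) with
Katz log-method intervals; a zero denominator cell is an error.
Bonferroni families are user-declared (`threshold = α / n_tests`).

## Synthetic cohorts

`generate_from_model` draws exactly from a given model (no
missingness) and backs parameter-recovery tests and the bootstrap.
`generate_cohort` emulates the study's data structure with defaults
that are the study conditions: 689 subjects; symptom sums on 9 visits
(0–24 months) and functioning on 3; class proportions 32/68, 41/15/44
and 57/43; mean curves through the published anchor values; ~30%
missing symptom assessments and ~34% missing functioning assessments.

Choices where the study reports nothing:

* **Within-class variances** are free parameters.  They were chosen so
  that (a) classification entropy stays in a realistic 0.4–0.8 band
  (published values: 0.81/0.43/0.51) and (b) the generating class
  counts are actually identifiable by BIC at N = 689 — random-effect
  SDs must stay modest relative to residual SDs, otherwise any
  enumeration procedure over-extracts by splitting the continuous
  heterogeneity into spurious classes.  The fluctuating
  negative-symptom class carries a pronounced
  decrease–increase–decrease cubic wave: its curvature is what
  distinguishes it from a random level shift, which intercept/slope
  random effects would otherwise absorb.  Under these defaults the
  positive-symptom classification is sharper than the published
  solution reports; identifiability was given priority over matching
  that index exactly.
* **Bounded scores** are generated with visit-level residuals drawn
  from a normal truncated to the score range, rather than by clipping.
  Clipping creates a point mass at zero that (i) manifests as a
  spurious near-zero-variance class and (ii) is not a feature the
  Gaussian mixture is meant to model; truncation keeps scores in range
  with only mild skew (flagged, as intended, by the normality check).
  The truncated probability mass is reported per outcome.
* **Cross-outcome coupling** uses a single shared standard-normal
  severity propensity; each outcome's class is a threshold
  discretization of `ρ_o u + √(1−ρ_o²) ε`.  The loadings are
  calibrated by bisection on exact bivariate-normal rectangle
  probabilities so that the worse-symptom → worse-functioning risk
  ratios match the published magnitudes (2.23 and 1.53).
* **Missingness** is a per-visit hazard rising with time whose logit
  shifts with an observed baseline covariate (employment status), so
  the missing-at-random assumption of FIML holds by construction.
  Subjects losing every visit keep their baseline assessment.
* **Covariates and distal outcomes** are drawn class-conditionally
  with effect sizes of the published magnitude (e.g. a binary
  early-response covariate with true odds ratio 4.5 for the better
  positive-symptom class, inside the published 3.4–5.5 range); the
  implied membership log-odds are available as ground truth.
  Item-level global scores (needed for sustained-remission criteria)
  are generated at months 18 and 24 by splitting the simulated sum
  across items with fixed shares plus rounding noise.

What passing tests on these cohorts do *not* show: real symptom scores
are small ordinal counts, assessments are irregularly timed,
missingness is never exactly MAR, and real class structure is not a
clean finite mixture.  Recovery results certify the pipeline's
correctness, not the clinical validity of any particular solution.

## Endpoints

Early response: score at month 3 at or below half the baseline (a
zero baseline is degenerate — response then means staying at zero).
Sustained symptomatic remission: all global items ≤ 2 (attention
excluded for the negative scale) at *both* months 18 and 24 — the two
scheduled visits bounding the 6-month window; no interpolation is
attempted between visits, mirroring how the criterion can actually be
verified on this schedule.  Functional remission: functioning > 60
(strict) at months 12 and 24.  Recovery: clinical (positive and
negative) plus functional remission.  Missing required visits make an
endpoint not evaluable (`NA`), never false.  Early response on total
symptoms thresholds the summed series over visits where both scales
are observed; requiring response on each scale separately is available
via `total_mode="both"`.

## Problem sizes used by the test suite

The acceptance suite runs at desk scale: likelihood oracle on 100
random instances (N ≤ 5, T = 3); parameter recovery at N = 600 over
20 seeds; structure recovery on 20 default cohorts (N = 689) per
topology with 49 bootstrap replicates, 4 random starts per fit and
truncated EM (tolerance 3e-7, 150 iterations) — decisions rest on BIC
margins far larger than the resulting log-likelihood error; LRT
calibration with 200 repeats × 99 replicates at N = 250.  These sizes
are the package's own choices for routine verification; all protocol
knobs scale up to the study settings.

## Known limitations

* Gaussian outcomes only; no skew-t or censored-outcome estimation
  (non-normality is detected and flagged, not corrected).
* No autoregressive residual structures or time-varying covariates.
* Wald standard errors condition on the estimated classification;
  no sandwich or profile-likelihood intervals.
* The 3-step implementation is the fixed-logit (ML) variant; BCH
  weighting is not provided.
* Joint (multivariable) covariate models are out of scope — covariates
  enter one at a time, as in the analysis the package reimplements.
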