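# growthmix

Latent growth mixture modeling of longitudinal clinical outcomes —
trajectory-class discovery, staged model selection, and 3-step
covariate analysis for cohort studies such as 2-year first-episode
psychosis follow-ups.

## The problem

Clinical cohorts followed over months or years are heterogeneous: some
patients improve rapidly, some fluctuate, some stay severe.  Latent
growth models describe a repeatedly measured outcome `y_i(t)` (a
symptom-severity sum, a 0–100 functioning score) as arising from `K`
latent trajectory classes.  Within class `k`,

```
y_i(t) = Σ_j β_kj t^j + z(t)'b_i + ε_it ,
b_i ~ N(0, Ψ_k),   ε_it ~ N(0, θ_kt),   P(class k) = π_k
```

with polynomial mean curves, optional random effects `b_i` on the
intercept and linear slope, and residual variances that may vary over
time and/or classes.  The family spans the single-class growth curve
model (GCM), group-based trajectory models (GBTM, no random effects),
latent class growth analysis (LCGA, relaxed residuals), and growth
mixture models (GMM) with class-invariant or class-variant `Ψ`.
Missing assessments are handled by full-information maximum likelihood
(FIML): each subject contributes a multivariate normal density
restricted to their observed visits, valid under missing-at-random.

`growthmix` implements, end to end:

* the FIML mixture likelihood, posterior classification, and fit
  indices (BIC, scaled entropy, average posterior probability of
  assignment);
* maximum-likelihood estimation by closed-form EM (random effects
  integrated via the Woodbury identity) with SQUAREM acceleration, an
  Mplus-style replicated random multistart protocol, and quasi-Newton
  polishing;
* the four-stage model-building strategy: single-class baseline →
  GBTM class enumeration (BIC + parametric bootstrap likelihood ratio
  test + 5% minimum class share) → residual-variance relaxation →
  stepwise random-effect addition, followed by Wald-test pruning of
  non-significant polynomial terms and Mardia within-class normality
  checks;
* the manual 3-step covariate analysis: misclassification logits
  extracted from the classification, then multinomial membership
  regressions and distal-outcome Wald tests with the measurement model
  held fixed, plus cross-trajectory risk ratios and Bonferroni
  correction;
* clinical endpoint derivation (early response, sustained symptomatic
  remission from global items, functional remission, recovery) and the
  >30%-missing attrition filter for sensitivity analyses;
* a synthetic cohort generator with full ground truth: three linked
  outcomes on the study's visit schedules, latent classes coupled
  through a shared severity propensity calibrated to published
  risk-ratio magnitudes, class-conditional covariates and distal
  outcomes, and missing-at-random dropout.

## Worked example

Generate a 689-subject synthetic cohort, run the staged selection on
the positive-symptom outcome, and relate the classes to an
early-response covariate and to the functioning trajectories:

```python
import numpy as np
import growthmix as gm

cohort = gm.generate_cohort(gm.default_config(n_subjects=689, seed=2))
protocol = gm.StartProtocol(n_starts=8, n_final_stage=2, polish=False,
                            max_doublings=1, em_tol=3e-7, em_max_iter=200,
                            replication_tolerance=1.0)
config = gm.SelectionConfig(max_classes=4, lrt_replicates=49)
fitted, audit = gm.stepwise_select(cohort.outcomes["saps"], preset_poly_order=3,
                                   config=config, seed=2, protocol=protocol)

logits = gm.misclassification_logits(fitted.posteriors, fitted.modal_assignment)
effect = gm.predict_membership(
    fitted, logits, cohort.covariates["early_responder"].to_numpy(float),
    reference_class=1, covariate_name="early_responder")[0]
```

A session running this selection and printing the class curves, the
early-response odds ratio and the cross-trajectory risk ratio against
the functioning classes produced:

```
selected: LCGA K = 2 orders = (3, 3) residuals = FREE_OVER_CLASSES
loglik = -9546.1  BIC = 19164.0  entropy = 0.97
class counts: [255 434]  APPA: [0.99 0.99]
class 0 mean at months 0/3/6/12/24: [3.1 2.5 2.2 2.1 2. ]
class 1 mean at months 0/3/6/12/24: [9.2 6.1 4.4 3.9 4.3]
early response OR (stable-low vs fluctuating) = 3.27 95% CI [2.33, 4.60]  p = 7.3e-12
RR (worse functioning | fluctuating vs stable-low) = 1.85 [1.45, 2.35], p = 5.5e-07
```

The pipeline recovered the generating two-class structure: a
stable-low class (baseline ≈ 3, settling near 2) and a fluctuating
class (baseline ≈ 9, dropping then hovering near 4), with
class-specific residual variances picked up at the residual-relaxation
stage.  Early responders have ≈3-fold higher odds of the stable-low
trajectory, and members of the fluctuating class carry an ≈1.9-fold
risk of the worse functioning trajectory — both reflecting the
association strengths built into the generator.  The full audit trail
of every candidate model (BIC, entropy, APPA, smallest class share,
LRT p-values, decisions) is in `audit.to_frame()`.

The same analysis runs from the shell:

```bash
growthmix simulate --n-subjects 689 --seed 2 --out cohort
growthmix select cohort/saps.csv --order 3 --max-classes 4 --seed 2
growthmix run-all --seed 2 --out run_seed2
```

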