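# Methods

## Synthetic cohort generator

The generator's job is to emulate the statistical structure a maturity-
offset validation study relies on, with a known ground truth.

**Growth law.** Each boy's true stature follows Preece–Baines model 1,

    h(t) = h_adult − 2 (h_adult − h_theta) / (exp(s0 (t − θ)) + exp(s1 (t − θ))),

a five-parameter family with a realistic adolescent velocity peak.  The
true APHV is defined by the curve — located by a 0.01-yr grid plus bounded
Brent refinement (tolerance 1e-6 yr) on the analytic velocity — not by the
population draw.  Because age enters only through t − θ, the peak age is
exactly translation-equivariant in θ; θ is therefore calibrated so that the
curve's peak matches a target APHV drawn from N(13.60, 0.85) yr truncated
to [11.5, 15.8].  One degeneracy is worth knowing: as s1 → s0 the curve
collapses to an exponential approach with monotone velocity and no spurt at
all, so near-equal rate constants raise a degenerate-curve error rather
than returning a peak.

**Shape-parameter population** (chosen once as field-realistic values,
all overridable in `CohortConfig`): h_adult ~ N(177, 6) cm;
h_adult − h_theta ~ N(14, 1.5) cm; s0 ~ N(0.112, 0.010) clipped to
[0.07, 0.16] /yr; s1 ~ N(1.25, 0.12) clipped to [0.8, 1.8] /yr.

**Design.** Baseline age uniform on [10.98, 12.94] yr; subsequent visits at
+1.0 yr with ±0.05 uniform jitter; per-visit retention (58, 58, 58, 55, 40)
achieved by non-informative dropout (randomly chosen subjects lose their
latest visits — so three subjects retain only three visits, which the
growth model accepts).  Dropout that depends on maturity status is not
modelled; the config structure leaves room for such variants.

**Body composition.** Sitting height = height × ratio, with the ratio
rising logistically from 0.510 to 0.527 (scale 1.5 yr) in maturity offset
(age − true APHV), plus N(0, 0.004) noise, clipped to [0.49, 0.55] as a
hard physiological guard.  Weight comes from a BMI trajectory
17.5 + 0.55·offset + N(0, 1.2), floored at 12 kg/m².  These simple
maturity-anchored forms give the Mirwald predictors realistic joint
behaviour (taller, heavier, higher trunk-proportion boys are closer to
their spurt); they do not attempt to model body composition per se.

**Measurement error.** Technical errors of measurement (0.27 cm height,
0.31 cm sitting height, 0.47 kg weight) are treated as SDs of additive,
independent normal noise — no systematic observer drift, no digit
preference.

What passing tests on this generator do *not* show: robustness to
real-data features such as seasonal measurement timing, informative
dropout of late maturers, non-Gaussian error tails, or ethnic variation in
trunk/leg proportions.

## Shape-invariant growth model

The model is h_ij = α_i + f((t_ij − β_i)·exp(γ_i)) + e_ij with
(α, β, γ) jointly normal (covariance D) and e ~ N(0, σ²).  f is a natural
cubic regression spline (truncated-power construction, analytic
derivatives) with df = 5 basis columns beyond the intercept — four or five
visits per subject leave the pooled curve well resolved at that
resolution — and knots at even quantiles of the transformed ages.

**Estimation** follows the classical first-order (Lindstrom–Bates)
approach, alternating:

1. spline coefficients by least squares at the current transformed ages
   (heights are centred internally, which also makes the fit equivariant
   to adding a constant to all heights);
2. per-subject random effects by penalised Gauss–Newton
   (Levenberg–Marquardt on residuals augmented with the Cholesky factor of
   D⁻¹);
3. variance components by quasi-Newton (L-BFGS-B over log-Cholesky(D) and
   log σ²) maximisation of the marginal likelihood of the Gauss–Newton
   pseudo-data z_i = r_i + J_i b̂_i ~ N(0, J_i D J_iᵀ + σ² I).

The reported log-likelihood is this linearised marginal likelihood.  The
iteration trace keeps only improving states, so it is monotone by
construction, and the fit returns the best state seen.  Convergence is
declared after two consecutive cycles whose log-likelihood changes by less
than tol·(1 + |ll|) with tol = 1e-5; a relative criterion is used because
the alternating scheme has a long geometric tail in which absolute changes
shrink slowly without the estimates moving meaningfully.

Two stabilisers matter in practice.  First, the velocity effect γ is held
at zero for the first 10 iterations ("alignment warm-up") while the
covariance stays at its prior (only σ² tracks the residuals); releasing all
three effects from the start lets β and γ absorb curve misfit before the
mean curve has sharpened, which can strand the fit in a flat-curve local
optimum.  Second, the spline knots are frozen after iteration 15 so the
objective stops shifting under the optimiser.  If the γ variance collapses
(< 1e-7) after warm-up, the model is refit with γ fixed at zero and a
warning — the singular-covariance fallback.

**APHV extraction.**  x* maximises f′ on the transformed-age range trimmed
by 2% per edge (boundary-spline artefact guard), via a 0.001-yr grid plus
bounded refinement; APHV_i = β_i + x*·exp(−γ_i).  Subjects whose APHV
falls outside a plausibility window (default 10.5–17 yr) or outside the
cohort's observed age range are flagged, not dropped; the pipeline excludes
flagged subjects and reports them.  The flag is deliberately based on the
cohort-wide empirical age range: a per-subject range would flag every late
maturer who left the study early even when their estimate is sound.

**Known limitation.**  A subject whose spurt lies mostly beyond his own
observed ages (a late maturer who drops out after visit 3) has a weakly
identified APHV; the estimate can be badly wrong yet land inside all
plausibility screens.  This mirrors the real design's vulnerability and is
visible in some seeds of the generator.  On the default cohort, per-subject
APHV is recovered with RMSE ≈ 0.19 yr against generator truth.

## Prediction equations and records

Coefficients are carried exactly as published (Mirwald: −9.236, 0.0002708,
−0.001663, 0.007216, 0.02292; Moore: −7.999994, 0.0036124; SEEs 0.592 and
0.542 yr as metadata).  Units are fixed at cm/kg/decimal years; the
weight-by-height ratio is kg/cm and is multiplied by 100 — the historically
mis-applied step, asserted by an analytic perturbation test.  Inputs are
used at stored precision; CA outside [8, 18] yr is an error, not an
extrapolation.  Prediction records enforce the identities
CA − offset = APHV and diff = predicted − observed APHV by construction.

## Classification and agreement

Timing cutoffs are recomputed from the analysed sample (mean ± 1 SD of
per-subject observed APHV), never hard-coded; with the reference moments
13.60 ± 0.85 they are 12.75 and 14.45 yr.  Outer groups use strict
inequalities, so boundary values are "average".  Status bands and the
±0.5 yr agreement comparison are inclusive at the boundary (a declared
convention; the reference text does not say).  Displayed percentages are
integers under round-half-up.  Empty cells report a blank percentage, not
zero.

## Deming regression

`lam` is the ratio of measurement-error variances (default 1: both APHVs
equally error-prone; not stated by the reference, hence configurable).  The
weighted scheme uses proportional-error weights 1/x̂² with
x̂ = (x + λ(y − a)/b)/(1 + λ/b²), iterated to slope stability (1e-10);
an unweighted mode is provided for sensitivity analysis.  At λ = 1 the
unweighted estimator equals orthogonal (major-axis) regression exactly and
axis-swapping inverts the line algebraically; the weighted variant inverts
only up to the weight asymmetry (the weights follow the latent x estimate),
which is on the order of 1% on realistic data.  Standard errors use the
delete-one jackknife with 95% limits from Student's t on n − 2 df.
Intercept limits excluding 0 flag systematic, slope limits excluding 1
proportional differences.

## Mixed-model ladder

Estimation is delegated to statsmodels MixedLM with maximum likelihood
(`reml=False`), so likelihood-ratio tests on fixed effects are valid; the
ladder is unconditional means (random intercept) → unconditional growth
(linear time, random intercept + slope) → + maturity group → + group × time.
Time is the visit index centred at visit 1, entered linearly (consistent
with random slopes; a categorical-time variant would need a different
ladder).  Missing visits are handled by ML under missing-at-random.
Parameter counts for LRT degrees of freedom include free (co)variance
components.  Conditional F statistics with software-specific denominator
degrees of freedom are not reproduced; LRTs (primary) and Wald z per
coefficient are reported instead.

## Problem sizes

Defaults throughout are the study's own: 58 subjects, 269 records.  The
machinery calibration checks use 200 replicates of 200 × 5 subjects for
mixed-model parameter recovery and 500 replicates of 40 × 4 for the LRT
null-rejection rate (random-intercept models, a truly absent three-level
factor, α = 0.05) — sizes at which the chi-square asymptotics are already
accurate.  The full test suite runs in about three minutes on one CPU.
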