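# Methods

`apotraj` estimates life-course trajectories of cardiometabolic risk
factors (systolic/diastolic BP, BMI, total and HDL cholesterol, glucose)
in women, contrasted by their history of adverse pregnancy outcomes
(APOs), and ships a calibrated synthetic electronic-health-record cohort
so the whole pipeline can be validated by parameter recovery without any
licence-restricted data.

## The statistical model

For woman *i*, measurement *j* of one outcome, the fitted model is a
two-level linear mixed model with a woman-level random intercept:

    y_ij = x_ij' beta + u_i + e_ij,
    u_i ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2).

The fixed-effect design on the relative-time axis (t = years since the
start of the first pregnancy, negative before it) is

    intercept + f_1(t) .. f_d(t)                (fractional-polynomial basis)
    + A (exposure-group indicators) + P (post indicator, t > 0)
    + all two-way products f_k A, f_k P, A P
    + all three-way products f_k A P
    + adjustment covariates,

so each exposure group has its own pre- and post-pregnancy shape.  On
the age axis the design is `f(age) + A + f(age) x A + covariates` with no
pre/post terms.  Adjustment covariates are age at first pregnancy,
deprivation-quintile indicators, ethnicity indicators, parity (truncated
at 5), ever non-singleton pregnancy, ever-smoking, three medication
ever-flags, and — for glucose only — the fasting flag.  Categorical
covariates enter as indicator sets with the most frequent level as
reference; constant columns in a subgroup are dropped.

### Fractional polynomials

The basis uses the conventional power set S = {-2, -1, -0.5, 0, 0.5, 1,
2, 3} on a positive argument x, with power 0 read as ln x and a repeated
pair (p, p) read as (x^p, x^p ln x).  Degree 1 gives 8 candidates,
degree 2 gives 36 (8 repeated + 28 distinct pairs), 44 in total.

Because t spans [-10, +15] years, t is first mapped through an affine
positivity transform x = (t - shift)/scale with shift = min - margin and
scale chosen so x <= 2.5.  The margin is 5 years: with a 1-year margin
the pre-pregnancy window maps to x in (0.1, 1.1), where bases such as
{x^2, x^2 ln x} degenerate (they cannot produce a linear slope near the
x -> 0 singularity) and near-tied candidates disagree by ~0.1 mmHg at
the window edge; with margin 5 the fitted range is x in [0.42, 2.5] and
the surviving candidates agree to < 0.04 mmHg everywhere.  The constants
are stored in the FP specification and reused verbatim at prediction
time.  The age axis uses age/10 (decades), the conventional scaling.

### FP selection

Powers are selected on a baseline model — FP terms, FP x post terms,
exposure main effects, post indicator, covariates, random intercept —
and then frozen before the interaction design is built, so selection
does not leak into group contrasts.  The FP x post terms are included so
candidate shapes are compared under the same pre/post flexibility the
final model has; without them selection favours whichever basis best
mimics a kink at t = 0 rather than the underlying shape.  Within each
degree the minimum-deviance candidate wins (ties break to the earlier
enumeration position); degree 2 is preferred over degree 1 only when its
deviance improvement exceeds the chi-square(2 df, 5%) critical value
5.99 — the standard fractional-polynomial function-selection test.  A
plain minimum-deviance rule cannot prefer degree 1, since every degree-2
model containing the true degree-1 shape fits at least as well.

### Estimation

Everything is maximum likelihood (not REML) so deviances are comparable
across fixed-effect structures during selection.  The random-intercept
likelihood is profiled over the variance ratio psi = sigma_u^2 /
sigma_e^2: given psi the within-woman covariance is compound-symmetric,
so GLS beta and the profiled sigma_e^2 are closed forms in per-woman
sufficient statistics (cross-products and group sums), and one
likelihood evaluation costs O(G p^2).  The profile is minimised on an
81-point log grid over psi in [1e-8, 1e6] followed by bounded Brent
refinement (tolerance 1e-10 in log psi); psi = 0 is checked explicitly
and boundary solutions are flagged.  sigma_e^2 is floored at 1e-12 so
noise-free verification data remain fittable.  Women with a single
measurement are retained; they inform the fixed effects and the residual
variance.

The random-slope variant (sensitivity analysis for systolic BP) adds a
2x2 unstructured covariance for (intercept, slope on the transformed
time); it is parameterised by the Cholesky factor of G/sigma_e^2,
profiled the same way via Woodbury identities, optimised by Nelder-Mead
from three starts, and never reports a worse deviance than the nested
random-intercept fit.

Unit tests verify the estimator against a dense-covariance brute-force
maximiser (agreement to 1e-6 in beta, variances and deviance), against
closed-form balanced one-way ML expressions, and against an independent
mixed-model implementation.

### Prediction

Trajectories are population-average predictions x'beta at the average
observed covariate levels of the fitting rows, with Wald 95% intervals
x'beta ± 1.96 sqrt(x' V x) using the model-based fixed-effect
covariance V = sigma_e^2 (X' W X)^-1.  Contrast curves between groups
use the same quadratic form on the difference vector; covariate means
cancel exactly.  The post indicator at a grid point is 1 iff t > 0
(t = 0, the first day of the first pregnancy, counts as pre).

## Exposure derivation

Woman-level any-pregnancy flags are ORs over pregnancies (missing when
underivable in every pregnancy, e.g. preterm-birth and size-for-
gestational-age flags without hospital linkage; missing contributes
zero to counts).  The APO count sums, over all pregnancies, occurrences
of gestational hypertension, preeclampsia, gestational diabetes,
preterm birth (either type), SGA, LGA and stillbirth — one pregnancy
with preeclampsia and SGA contributes two — plus one if the woman had
3+ miscarriages (not necessarily consecutive); categories are 0/1/2/3+.
One or two miscarriages and congenital anomalies never count.  A woman
is "healthy-only" for the any-APO contrast iff her count is 0, every
pregnancy ended in a live birth and no anomaly is recorded; women whose
only events are 1-2 miscarriages, anomalies, or who lack a live birth
are unclassifiable and excluded from that contrast.  SGA analyses drop
LGA women from the comparator and vice versa; the preterm-birth analysis
has three groups (none / spontaneous / medically indicated, with
indicated taking precedence for women who experienced both across
pregnancies).  By default a recurring APO counts once per occurrence
(`distinct_types=True` switches to once per type).

The analysis table for one outcome drops measurements taken during any
pregnancy (interval check against the pregnancy table), restricts to the
window [-10, +15] years (configurable), drops rows with a missing
deprivation quintile, and applies the eligibility mode: `any` (at least
one measurement, the default) or `pre_and_post` (at least one before and
one after the first pregnancy — the sensitivity analysis).

## The synthetic cohort

The generator emulates the structure of a UK primary-care pregnancy
cohort; it is a *verification* cohort with known ground truth, not a
faithful patient-level simulator.

**Covariates.** Age at first pregnancy is a truncated normal on [12, 55]
whose parent parameters are solved at run time so the realised mean and
SD are exactly the configured 27.1 (6.6) years.  Deprivation quintile
(21.2/20.4/20.9/21.6/16.0%, 0.1% missing), ethnicity (86.5% White),
ever-smoking (45%), parity (41.6/28.1/15.0/8.0/7.2% for 1/2/3/4/5+),
non-singleton history (1.1%) and the three medication flags (5.9/0.3/
1.0%) are independent categorical draws.  Covariates are independent of
APO status: the generator reproduces the published marginals, not
confounding.

**APOs.** A latent standard-normal frailty z per woman shifts the logits
of all APO indicators, inducing co-occurrence.  Miscarriage is drawn per
pregnancy with probability expit(a + lam z); (a, lam) are solved by
quadrature so the woman-level any-miscarriage (18.6%) and
3+-miscarriage (0.6%) rates hit their targets.  The other APOs are
woman-level indicators expit(a_k + lam_k z) attached to one randomly
chosen (birth) pregnancy; birth-requiring APOs (preterm birth, SGA,
LGA, stillbirth) are only drawn for women with at least one
non-miscarried pregnancy and their solve includes that availability
factor, so all marginals match their targets by construction at any
loading.  SGA/LGA and spontaneous/indicated preterm birth are drawn
mutually exclusively from a single uniform.  A woman-level
hospital-linkage indicator (54.5%) masks preterm and SGA/LGA flags to
missing, mirroring the fact that the published count distribution is
only arithmetically consistent with those flags being underivable for
the unlinked fraction.  The two frailty loadings (0.2169 for the
hypertensive/metabolic cluster, 2.7438 for the birth-outcome cluster)
were calibrated once, by deterministic least squares of the
quadrature-implied APO-count distribution against the published
71.7/21.2/5.7/1.5% cells, and frozen in the default config; the implied
cells agree with the targets to within 0.23 percentage points
(structural limit of a single-factor model with fixed marginals).

**Pregnancy timing.** First pregnancy starts at t = 0; gestation is
0.75 y for births and 0.30 y for miscarriages; inter-pregnancy gaps are
uniform on 1-4 y.

**Truth curves.** Each (outcome, APO-count group) has a true mean curve
defined by four anchors: t = -10, 0, +10, +15.  For systolic BP the
t = ±10 anchors are the published predicted values (112.9/115.1/116.8/
119.6 mmHg pre; 119.5/121.2/124.3/127.1 post); the t = 0 and +15
anchors, and all anchors for the other outcomes, are package-chosen
plumbing: value at 0 = pre + 0.55 x (post - pre) and value at 15 = post
+ 0.5 x (post - pre), giving a steeper rise through the childbearing
years and continued acceleration afterwards — clinically plausible and,
importantly, enough curvature that FP selection is well identified (with
a nearly linear truth all 44 candidates tie and selection is arbitrary).
The curve is one quadratic per pre/post segment, exact at every anchor,
value- and slope-continuous at t = 0, and monotone for the default
anchors.  A quadratic per segment lies exactly inside the fitted
degree-2 FP interaction family, so anchor-recovery tests measure
estimation error, not interpolation mismatch — this is why quadratics
were preferred over shape-preserving cubic interpolation, whose local
slope rules generate shapes outside every FP basis.

**Measurements.** Counts per woman and outcome are Poisson with mean =
base rate x an APO-count-group multiplier (1.0/1.15/1.3/1.45), times
uniform on the window — a homogeneous observation process with
APO-dependent intensity, reproducing the published direction (women
with APOs are observed more) and the median of 6 BP measurements per
woman; base rates are 6.0 (BP), 3.0 (BMI), 0.25 (cholesterol), 0.62
(glucose), the last two also matching the published fractions with any
measurement (~22% and ~46%).  A measurement value is truth curve +
mean-centred covariate effects + woman intercept + residual; because
effects are centred, the group truth curve *is* the population-average
curve and predictions at average covariates estimate it directly.
Glucose gets a fasting flag (p = 0.5) with a -0.5 mmol/L centred
effect.  Values outside plausibility bounds (e.g. SBP 60-250 mmHg) are
rejected and the residual redrawn.  In-pregnancy measurements are
generated and flagged — excluding them is the pipeline's job.

**Noise scale.** The default variance components are deliberately small
(SBP: intercept SD 1.2, residual SD 2.5 mmHg; other outcomes scaled
similarly).  The cohort's purpose is to detect systematic error: at the
default verification size of 20,000 women the rarest group (3+ APOs,
1.5% = ~300 women) then has a Monte-Carlo SE of ~0.2 mmHg at the window
edge, so a 0.5-mmHg recovery tolerance tests bias rather than noise.
With heterogeneity at the scale real primary-care BP data show (both
SDs near 9 mmHg) that group's anchor SE would be ~1.2 mmHg and recovery
checks at this cohort size would be uninformative.  Set
`truth.noise_scale` (a multiplier on both SDs) to explore realistic
regimes.

**What the generator does not emulate** — and hence what passing tests
do *not* establish about real data: confounding between covariates and
APO status; informative observation related to the *unobserved* outcome
level (rates depend only on the derived APO group, so estimates are
unbiased by construction — the real "information presence" bias is
absent); within-woman correlation across different outcomes;
overdispersed visit counts (the published IQR 3-12 is wider than
Poisson); terminations and unknown pregnancy outcomes; coded-event
streams; real recurrence of the same APO across pregnancies (each APO
occurs at most once per woman, which is what makes the published count
distribution attainable).

## Validation design and problem sizes

The acceptance-style tests run: a single 20,000-woman pipeline requiring
every systolic-BP anchor within ±0.5 mmHg; 20 replicate pipelines at
20,000 women requiring each anchor's mean error within 3 Monte-Carlo
SEs of zero; dense-oracle equivalence at 30 women; 50 selection
replicates at 2,000 women from an x^(-1/2) truth (coefficient 15,
residual SD 1.5, ~4 measurements per woman — a strong, identified
signal) requiring ≥80% power recovery; generator calibration at 100,000
women at 3 Monte-Carlo SEs (count-distribution targets taken from the
published counts over the published denominator); and
nesting/degeneracy checks.  These sizes keep the full suite near ten
minutes on one CPU while leaving every check statistically sharp.

## Known limitations

* Wald intervals condition on the estimated variance ratio; no
  small-sample or sandwich correction is offered.
* FP selection uncertainty is not propagated into the intervals (powers
  are treated as fixed once chosen), as is standard for this method.
* The random-slope fit uses a derivative-free optimiser; for very large
  cohorts it is noticeably slower than the profiled intercept-only fit.
* `eligibility="pre_and_post"` conditions on future observation and is
  offered only as the sensitivity analysis it replicates.
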