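# Methods

`dipro` implements two complementary generative models of disease
progression for cohorts of mutation carriers and non-carrier controls —
an event-based model (EBM) of the *order* in which biomarkers go
abnormal, and a differential-equation model (DEM) of *when* they do —
together with the preprocessing, staging and onset-prediction machinery
that connects them, and a synthetic-cohort generator that provides
ground truth for validation. This note records the models, their
assumptions, the defaults, and the design decisions taken where the
design was genuinely open.

## Synthetic cohorts

Each subject is a mutation carrier or a non-carrier. Carriers carry a
latent disease clock τ (years from symptom onset; negative before
onset), drawn uniformly over a window (default −30 to +10 years) at
baseline. Uniformity is a deliberate choice for *stage coverage* in
validation studies, not demographic realism: it guarantees observations
across the whole progression. Each biomarker follows a logistic
sigmoid in τ,

    μ_b(τ) = normal_b + (abnormal_b − normal_b) · σ(rate_b · (τ − midpoint_b)),

with observation noise interpolating between the normal and abnormal
standard deviations along the same sigmoid, so far-presymptomatic
carriers are statistically indistinguishable from non-carriers.
Midpoints strictly increase along the configured event sequence, which
is the ground-truth ordering all cross-sectional inference is checked
against; the closed-form time for a noise-free sigmoid to cross from
25% to 75% of its range, 2·ln(3)/rate, is the ground-truth transition
time for longitudinal inference.

Measurement noise is decomposed into a stable per-subject offset plus
independent visit-level error (default: 75% of the noise variance is
subject-level, i.e. test–retest ICC 0.75, typical of imaging and fluid
biomarkers). The marginal distribution at any visit is unchanged by
this split — every cross-sectional property is as if noise were drawn
fresh — but within-subject visit-to-visit scatter is realistic, which
matters for rate-of-change estimation; without it, slopes over 1–3
years of follow-up are pure noise for every biomarker. The stable
offsets also introduce honest regression dilution into the rate-versus-
value regression (noisy x), which elongates estimated trajectories —
a known property of this class of model that the estimates inherit.

Visits: 1–4 per subject (configurable probabilities), ≈1.1 years apart
by default. Global CDR is derived from τ (0 before onset, 0.5 in the
first 3 post-onset years, ≥1 after; the 3-year window is arbitrary but
fixed). Covariates (age, sex, education, total intracranial volume) are
drawn independently of τ by default, so covariate adjustment can be
validated without disease-covariate leakage; additive covariate effects
are injected per biomarker, centred at the population covariate means so
marginals keep their configured levels. Missingness is drawn per
modality per visit, completely at random. Familial onset surrogates are
emitted per row: `parental_eyo` = τ + a per-subject N(0, 5 y) error and
`mutation_eyo` = τ + N(0, 8 y), mirroring a parental estimate and a
coarser mutation-type average. Converters — carriers with CDR 0 at
baseline that becomes non-zero later — receive an observed onset age.

The default 24-biomarker panel mimics a multimodal familial-AD battery
(five amyloid-PET SUVRs, three CSF analytes, three FDG-PET SUVRs,
eleven MRI volumes/thicknesses, MMSE) in natural units, with
symptomatic-versus-control effect sizes of 2–3 normal-SDs and three
null markers (entorhinal, thalamus, caudate volumes) for selection
procedures to reject. Units are natural (SUVR, pg/ml, mm³, points)
rather than z-scores so that positivity-assuming rules such as the
coefficient-of-variation exclusion behave as on real data.

What the generator does **not** emulate: between-biomarker noise
correlation, subject-specific trajectory shapes (random slopes),
non-monotone dynamics (e.g. CSF amyloid-β rise-then-fall),
visit-driven missingness, and mutation-type effects. Passing tests
therefore demonstrate correctness of the estimators under a
well-specified monotone single-clock model, not robustness to those
violations.

## Preprocessing

*Covariate adjustment.* Per biomarker, a linear model on non-carrier
**baseline** rows (one independent observation per subject; repeated
visits share the subject-level noise offset and would inflate
significance) with backward elimination: drop the covariate with the
largest p-value until all are below 0.05. TIV is offered only to MRI
volume-type biomarkers. The fitted prediction (intercept included) is
subtracted from all subjects' values, so non-carrier residuals centre
at zero; fitting on controls only avoids regressing out disease
signal. An empty covariate list is the identity.

*Disease-signal selection.* Welch's two-sample t-test per biomarker
between baseline non-carriers and baseline symptomatic carriers
(CDR > 0.5), retained iff p < α_family / N (default 0.01/N,
Bonferroni). A paired test is inapplicable to independent groups.

*Differential data.* Per carrier and biomarker with ≥2 non-missing
visits, the OLS slope of value against years-from-baseline and the mean
of the fitted line are one (x, dx/dt) point. Exclusions, each logged
with exactly one reason code: `too_few_visits`; `cv_too_large`
(within-subject coefficient of variation of the **raw** values above
0.5 — residualized values have near-zero means and no meaningful CV);
and `normal_nonprogressing` — points on the normal side of a boundary
found by a deterministic 1-D two-Gaussian mixture of carrier baseline
values (initialized at the 25th/75th percentiles; boundary at the
posterior-responsibility crossing; fallback to the midpoint of the
half-sample medians) whose slope contradicts the progression
direction. The rule removes contradictory normal-range points only;
abnormal-side points are kept whatever their slope.

## Event-based model

Progression is a fixed sequence S of N events; subject j at unknown
stage k has abnormal values for the first k events of S and normal
values for the rest. With event distributions p(x|E), p(x|¬E) the data
likelihood marginalizes the stage uniformly:

    P(X|S) = Π_j (1/(N+1)) Σ_k Π_{i≤k} p(x_{S(i)j}|E) Π_{i>k} p(x_{S(i)j}|¬E),

computed in log-space with a log-sum-exp guard and densities floored at
1e−250.

*Event distributions.* Normal component pinned to the non-carrier
baseline mean/SD and never updated; abnormal component and mixing
weight fitted on all carriers by bounded L-BFGS-B (three deterministic
starts). Constraints: σ_abnormal ≥ 0.1·σ_normal, and the abnormal mean
on the pathological side at least **one normal-SD** from the normal
mean — raised, when at least five symptomatic carriers are observed,
to half a normal-SD below their median. The floors resolve two real
identifiability problems of this heavily-overlapping mixture. First,
for late events with few abnormal carriers, an "abnormal" component
hugging the normal one with weight → 1 achieves the same likelihood as
the intended solution but poisons staging; with the floor the fit lands
on the branch where the normal-component weight approaches its bound
instead (the behaviour also produced when carriers are entirely
normal). Second, when transitions are gradual, the continuum of
mid-transition carriers makes the two-component model misspecified and
its maximum-likelihood fit shrinks the abnormal mean toward the normal
component while inflating its weight trade-off; anchoring at the
symptomatic level — which is what "abnormal" means in this model
family — removes that collapse. Both are constraints on the admissible
parameter region, not priors; the fit within the region is still
maximum likelihood.

*Inference.* Greedy ascent over single-event repositions from random
restarts (default 10; the first restart starts at input order, making
likelihood ties resolve to input order). Uncertainty by
Metropolis–Hastings over permutations with uniform prior and a
symmetric two-position swap proposal (any pair, not adjacent — simpler
mixing, same stationary law); defaults 10⁵ iterations, 10⁴ burn-in,
thinning 10; acceptance rates outside [0.02, 0.9] are logged.
Positional-variance matrices (event × position occupancy frequencies,
doubly stochastic by construction) summarize MCMC samples and, for
cross-validation, the ML sequences of subject-level bootstrap resamples
(resampled within carrier/non-carrier groups, 100 replicates by
default, event distributions refitted per replicate).

*Missing data.* A missing cell contributes one equal constant to both
hypothesis products, so it cancels from every likelihood ratio: masked
biomarkers cannot influence the relative ordering of the others
(verified exactly in tests) while the observed subset still informs it.

*Staging.* Stage posterior ∝ the k-terms above under the ML sequence;
assignment is the argmax with ties to the earlier (more conservative)
stage; all-missing rows get a uniform posterior and a flag.

Two design calculations worth recording. With N ≈ 12 events of effect
size d ≈ 2 and heavier-tailed abnormal components, even the *ideal*
measurement model assigns ~20% of controls a non-zero stage (one tail
value among twelve suffices), so "all controls at stage 0" is a
property of strongly separated panels (d ≳ 4.5); validation uses d = 6
for that property, matching the near-complete amyloid/CSF separation
seen in symptomatic familial AD. And ordering recovery is validated
under event-like transitions (25%→75% of the range in ~2 years,
comparable to the event spacing): with much more gradual transitions
the mixture misspecification above caps recovery at Kendall τ ≈ 0.88
however good the search — a property of the model class on
slow-transition data, not of this implementation (the ideal-component
model recovers τ ≈ 0.96 there).

## Differential-equation model

Rate of change as a function of value, f(x) = dx/dt, under a GP prior
with squared-exponential covariance

    k(x_i, x_j) = η² exp(−ρ² (x_i − x_j)²) + δ_ij σ²,

rates centred before fitting. Half-Cauchy hyperpriors with data-driven
scales: η, σ ~ HC(0, 2·sd(dx/dt)), ρ ~ HC(0, 4/range(x)). Default
inference is MAP in log-hyperparameter space (Nelder–Mead, three
deterministic starts, search confined to a generous box around the
prior scales) with Laplace sampling of the hyperparameters; full MCMC
over the hyperparameters (affine-invariant ensemble sampler, split-chain
statistic checked against 1.05) is available via `method="mcmc"`. The
MAP+Laplace default keeps ten-fold cross-validation and many-biomarker
pipelines at interactive speed, and its 50% predictive-interval
coverage is validated directly. One latent-function sample is drawn per
hyperparameter draw on a 200-point grid spanning the observed values
±10%; non-positive-definite covariances get an escalating jitter ramp
from 1e−8.

*Anchors.* Canonical normal = median biomarker value among asymptomatic
carriers at baseline; canonical abnormal = median at each carrier's
**first** symptomatic visit (CDR > 0), which defines t = 0.

*Trajectories.* Per sample, t_s(x) = ∫ du/f_s(u) from the canonical
abnormal level, by trapezoid on the grid with the anchor values
inserted as nodes (exact for constant rates); samples whose rate has
the wrong sign anywhere strictly between the anchors are rejected
(> 50% rejected raises, pointing at the exclusion rules — the same
failure the method shows on noisy CSF markers); integration truncates
where |f| < 1e−4 × value-range per year and such samples are excluded
from the transition-time density, with counts reported. The
transition time is T_s = |t_s(canonical normal)|; its empirical
distribution gives the cumulative probability of abnormality
C(t) = fraction of samples with −T_s ≤ t and the summary t₅₀ where C
first reaches one half. Each accepted trajectory is strictly monotone
by construction — the one-to-one value↔time assumption restricts the
method to monotone biomarkers.

A structural caveat: when every biomarker follows the *same* clock
with anchors defined as medians over that clock's population, measured
transition durations are equal by construction (both anchors map to the
same latent-time quantiles), so duration ordering carries no midpoint
signal. Ordered durations — as observed in real multimodal panels,
decades for amyloid versus a few years for hypometabolism — arise from
heterogeneous *dynamics*: early slow markers caught mid-course versus
late fast markers caught mid-transition at onset. The ordering-recovery
validation therefore pairs an early slow (rate 0.2/y) with a late fast
(rate 0.5/y) marker, midpoints 10 years apart.

## Onset prediction

Per biomarker, a subject's measurement is aligned to the average
trajectory (sample-wise alignment is available as an option); the
credible-interval width is the interquartile spread of sample times at
that value; the subject's estimated time from onset (ETO) is the
average of per-biomarker times weighted by inverse width, missing
biomarkers omitted. Robustness rules, both flagged per biomarker:
measurements covered by fewer than half of the trajectory samples are
treated as out of range and dropped (an IQR over a handful of covering
samples wildly understates alignment uncertainty), and measurements
beyond either canonical level are censored at that level — the
trajectory is anchored and validated only on the transition between
the levels, and in the flat tails a noise-sized value difference maps
to decades of spurious time. If all widths degenerate to zero, weights
fall back to equal.

Evaluation mirrors the held-out-converter design: converters are
excluded from every model fit; estimated versus actual
years-from-onset at baseline are summarized by RMSE and the adjusted
R² of the linear fit of estimated on actual (standard small-sample
correction), head-to-head against the parental and mutation-type
surrogates read from the cohort. ETO inherits a small systematic
earliness from the anchor being the first symptomatic *visit*
(interval censoring of onset between visits).

## Reproducibility and problem sizes

Every stochastic routine takes an explicit seed or generator; the
pipeline spawns per-stage seeds deterministically from one master seed
and writes a manifest (seeds, versions, selections, exclusion counts —
timings go to the log so the manifest is byte-reproducible). Rerunning
a configuration reproduces all numeric outputs exactly.

Validation studies run at deliberately moderate scale — cohorts of
60–350 carriers, 2–24 biomarkers, 10–150 posterior samples, 3–20
replicate seeds per property — chosen so each study has clear
statistical margin for the property it checks while the whole suite
remains interactive. `scripts/acceptance.py --seed S --out results.json`
re-runs all of them from scratch and writes the headline numbers.

## Known limitations

Single progression pattern per cohort (no subtypes or random effects);
monotone trajectories only; measurement noise is not deconvolved, so
transition times are dilution-elongated upper estimates; the
mutation-type surrogate is simulated, not a meta-analytic table; CDR is
generated by thresholding the latent clock, so clinical heterogeneity
is absent; MCAR missingness only.
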