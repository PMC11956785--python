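# Methods

## State space and coding rules

Four states ordered by disease burden: no disease (0), one disease (1),
multimorbidity (2), dead (3). Multimorbidity means at least
`threshold` (default 2) of the 14 included chronic conditions:
Alzheimer's disease, arthritis, asthma, cancer, diabetes, emphysema,
epilepsy, heart problems, HIV, hypertension, kidney problems,
psychological/psychiatric disorders, stroke, tuberculosis. Hypertension
is taken either from its indicator column or derived from per-wave mean
blood pressures: systolic ≥ 140 mmHg **and** diastolic ≥ 90 mmHg
**and** systolic − diastolic ≥ 15 mmHg, implemented literally. The
third clause is unusual (it reads as a pulse-pressure plausibility
filter); because its intent is ambiguous it can be disabled via
`require_pulse_gap=False`, but the literal rule is the default. A
missing pressure makes the condition *unknown*, not absent, and routes
the wave to the missing-data path.

Chronic conditions are treated as permanent, so states may never
decrease along a trajectory. Observed reversals (reported recoveries,
inconsistent self-report) are repaired by carrying the highest state
attained forward (`max` prefix scan) rather than dropping the person:
this preserves sample size and matches the chronicity semantics of the
model. A living observation after a death report is unrepairable and
raises. Waves with an incomplete disease block contribute no
transition; their flanking waves pair up.

Exclusion cascade, applied sequentially to the raw panel: individuals
observed at a single wave; individuals with fewer than two valid
interviews (alive with a complete disease block, or a death report);
individuals missing essential demographic or weight fields. The tally
class enforces initial − excluded = final by construction.

## Transition records

Each individual contributes one record per observed wave: a baseline
pseudo-transition (the first observed state counted as a
self-transition, representing pre-survey chronic status) plus one
record per consecutive pair of observed waves, carrying exact age at
origin, the person's covariates and design weight. Pairs spanning a
missed interview are treated as a single biennial transition by
default; `drop_gapped=True` restricts to adjacent-wave pairs (a
sensitivity, and the right choice when comparing fitted estimates with
generative truth, where a gapped pair compounds two transitions).
`include_baseline_pseudo=False` removes the baseline convention for the
same reason.

## Transition model

Per sex and per transient origin, a multinomial logit over the
admissible destinations (from no disease: all four states; from one
disease: itself, multimorbidity, death; from multimorbidity: itself or
death — a binary logit), reference category "remain in the same
state". The published equation defines the reference as the no-disease
destination, which is only well-formed from the no-disease origin;
reference-to-self is the natural generalisation consistent with the
structural zeros. Covariate sets: M1 = intercept + exact age (linear,
untransformed) + urban residence; M2 adds race (reference African);
M3 adds education (reference less-than-secondary); M4 drops the
smallest racial group (Asian/Indian), dichotomises education
(less than secondary vs secondary-or-more, post-secondary included in
the upper category) and enters the race × education interaction.

Fitting maximises the design-weighted log-likelihood by Newton–Raphson
with analytic score and Hessian and step-halving; convergence failures
(separation, single observed destination) raise with the origin named.
A destination with no observed transitions (typically zero deaths from
an origin) triggers a boundary warning and is held at a numerically
zero probability rather than chasing an infinite estimate.

**Variance–covariance.** The default is the weight-robust sandwich
estimator I⁻¹ (Σ wᵢ²sᵢsᵢ') I⁻¹ — the standard pseudo-likelihood
variance for survey-weighted estimation. With heterogeneous lognormal
weights the model-based information variance is anti-conservative
(pilot simulations: ~92% coverage of nominal 95% intervals, vs ~94–96%
for the sandwich), so "accounting for the survey design" selects the
sandwich; `cov_type="information"` (weights normalised to mean one)
remains available. Blocks across origins are treated as independent:
under the Markov assumption, records of the same person have
uncorrelated score contributions. The full vcov is block-diagonal over
origins and is what the delta method consumes.

## Life-table engine

Matrices P_k are built from predicted probability rows at each interval
start (option: midpoint), ages `start, start+2, …` strictly below the
truncation age. "Ages 20 to 85" therefore yields 33 matrices with the
last interval (84–86) counted in full; `final_interval_weight=0.5`
half-weights it to approximate the age-85 horizon exactly. Occupancy
convention: the state at an interval start earns the full two-year
step, so certain death in the first interval still yields 2.0 years.

Conditional expectancies are computed two ways and must agree to 1e-9:
(a) the fundamental matrix N = (I − U)⁻¹ of the age-expanded transient
chain (state × interval; the last interval has no onward transitions,
so the chain is absorbing and N is finite), and (b) forward
accumulation of occupancy vectors. The fundamental-matrix route is
primary; the forward route is the built-in cross-check. An independent
Monte Carlo trajectory oracle (100,000 paths in the acceptance suite)
checks the same quantities within 3 Monte Carlo standard errors; since
sixty simultaneous 3-SE checks will occasionally throw a pure-noise
outlier even for exact algebra, an exceedance only fails the test when
confirmed by a second, independently seeded oracle draw.

Origin weights are the design-weighted baseline-state shares of
individuals whose first observation falls in [start_age, start_age+10)
— ages 20–29 for the main analysis. The age-40 sensitivity shifts the
window to 40–49 by analogy (the source text does not state a window
for it). Weighted LE and MMLE are the corresponding convex
combinations of conditional expectancies; the percentage of LE with
multimorbidity is rounded half-away-from-zero to integers, expectancies
to one decimal, matching the published display precision.

## Confidence intervals

Delta method on the full coefficient vector: central finite differences
with step 1e-5 on the coefficient scale (the published derivation's
analytic gradients live in an external methods paper; numerical
gradients are robust and are validated against the Monte Carlo oracle
and by coverage simulation), variance g'Vg, normal quantiles. Negative
lower limits are set to zero and flagged `clamped`, since negative
expectancies are impossible. Intervals are computed for weighted LE and
MMLE; the percentage carries no interval.

## Synthetic panel generator

The generator *is* the study conditions: 18,030 adults by default, five
waves two years apart, baseline ages uniform on [20, 90] (the source's
age pyramid is not printed; uniform is the declared default, and it
makes the synthetic cohort older on average than a real survey sample
— synthetic LE levels are therefore lower than published ones, which
the package does not attempt to reproduce), covariate margins matching
the published baseline composition (60% female; 79.9% African, 14.8%
Coloured, 4.1% white, 1.2% Asian/Indian; education 46.2/41.6/12.2%;
50.2% urban), baseline states (0.697, 0.223, 0.080), lognormal(0, 0.5)
design weights, 15% independent per-wave interview non-response
(matching ~51% full-attendance over five waves), deaths reported by the
household at the next scheduled wave and exempt from individual
non-response, interview ages jittered ±0.5 years so the continuous age
covariate is exercised.

Generative coefficients use the M1 design. Intercepts are calibrated so
the reference profile (age 42, half urban) reproduces realistic
sex-specific biennial transition fractions (e.g. one-disease →
multimorbidity 0.113 for males, 0.122 for females; death from
multimorbidity 0.112/0.063); log-odds of death rise at 0.085 per year
of age, progression at 0.035, with small urban effects (+0.05
progression, −0.10 death). Disease identities are assigned by weighted
sampling without replacement with hypertension much the most common,
and blood pressures are drawn consistently with the hypertension flag
so both hypertension rules work on synthetic data.

What the generator does **not** emulate: household clustering and the
two-stage sample design (weights are i.i.d. inputs), calendar effects,
state-dependent attrition (available as a multiplier but off by
default, as no model for it is published), item missingness (off by
default), and any correlation between covariates and disease risk
beyond the modelled coefficients. Passing recovery tests therefore
demonstrates correctness of the estimation machinery under the model's
own assumptions, not robustness to the unmodelled features of real
survey data.

## Problem sizes used in validation

Parameter recovery uses three replicate panels of 50,000 individuals ×
5 waves (attrition 0, no baseline pseudo-records, so fitted and
generative dynamics are directly comparable); fitted LE/MMLE are
compared as the mean over replicates (single-panel Monte Carlo error is
~0.2–0.3 years) and Wald coverage is pooled over replicates, sexes and
coefficients. Interval coverage uses 500 replicates of 5,000
individuals (single-sex mix to double the effective stratum size). The
Monte Carlo oracle uses 100,000 paths per comparison in the acceptance
suite and 20,000 in unit tests.

## Known limitations

- Design-based variance for multi-stage samples (PSU/stratum) is out of
  scope; the sandwich treats records as independent.
- Gapped wave pairs are coded as biennial transitions, which inflates
  per-interval transition probabilities in proportion to the gap rate;
  `drop_gapped` quantifies the effect.
- The baseline pseudo-transition convention biases stay probabilities
  upward relative to a pure incidence sample; it is retained by default
  for fidelity to the published data construction.
- Truncation at 85 makes all expectancies conditional on the horizon;
  no attempt is made to close the life table above it.
- The monotone-coding repair assumes reported recoveries are
  measurement error, which over-states chronicity if genuine cures
  occur.
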