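# Methods

This note documents the models, the numerical choices behind them,
what the synthetic-data generators emulate, and the limits of what the
test suite can show. Probabilities are proportions throughout; ages
are exact years; the radix is 100 000.

## Abridged life tables

The default age grid is 0–1, 1–4, then 5-year groups with an open
interval at 90+ (configurable to 100+, giving 22 groups). Central
death rates m convert to probabilities by q = n·m/(1 + (n − a)·m) in
closed groups; the open group has q = 1 and L = l/m, so the
expectation of life at the open age is 1/m. Separation factors
(average years lived in-group by decedents): a0 = 0.3 when m0 ≥ 0.01,
else 0.1 + 20·m0 (a smooth low-mortality adjustment); 1.5 for ages
1–4; n/2 elsewhere. The rule is injectable; indicator-level results
are insensitive to it, which is also why exact replication of any
specific published table's columns is not attempted. `table_from_q`
inverts the conversion with m = q/(n − (n − a)·q); because the infant
separation factor depends on m0, the (a0, m0) pair is resolved by a
short fixed-point iteration (converges in 2–3 steps; tolerance 1e-15
on a0). The two constructors are exact inverses, which the suite
asserts to 1e-12.

Indicators are read off the survivorship column: 45q15 = 1 −
l(60)/l(15), 20q60 = 1 − l(80)/l(60), and e0 = T(0)/l(0).

## Log-quadratic system

Calibration is the two-stage procedure: per age group, ordinary least
squares of log10(m) on (1, x, x²) with x = log10(5q0) observed from
each corpus table; then the leading right singular vector of the
centred residual matrix becomes the unit-norm shape vector v,
sign-fixed so that the 15–60 sum of v is positive (positive k raises
adult mortality, which also makes the k-maps of 45q15 and −e0
increasing and lets a bracketing root finder match them).

Prediction honours the input 5q0 exactly: the infant rate comes from
the model equation and is converted to 1q0 through the separation
factor rule, and the 1–4 probability is then solved from
q4_1 = 1 − (1 − 5q0)/(1 − 1q0). Two consequences are worth stating
plainly:

* the (a, b, c, v) row for ages 1–4 never enters prediction. The
  fitted system still reports a fitted 1–4 row (it describes the
  corpus), but the synthetic generator marks that row non-generative
  (NaN in the truth record), and v(1–4) is fixed at 0 by excluding
  the group from the SVD. Parameter-recovery tests compare the
  generative rows.
* an input 5q0 smaller than the implied 1q0 is infeasible and is
  signalled, as is any predicted closed-group q ≥ 1.

Identifiability of the shape dimension: a component of the per-table
scores k lying in the span of the level design (1, x, x²) is
indistinguishable from a shift of (a, b, c). The corpus generator
therefore draws k uniformly and removes its design-space component —
the canonical gauge in which the generative parameters are the
identifiable ones and exact recovery is a well-posed check.

k-matching uses Brent's method. The nominal bracket is [−8, 8]
(doubled up to |k| = 32 before the target is declared out of range),
but large |k| can push closed-group probabilities past 1, so each
bracket end is first pulled back to the feasible region by halving.
Tolerances: 1e-9 absolute for probability targets, 1e-7 years for e0.
Out-of-range 5q0 inputs warn and extrapolate the quadratic; they are
never clamped silently.

## Modified-logit system

The logit convention is the classic Brass scaling Y = ½·ln((1 − l)/l)
on radix-normalised survivorship at the interior grid boundaries
(1, 5, …, open start); the standard Ys is the corpus mean. The
correction model is this package's own concrete design (the idea —
age-specific corrections driven by child and adult deviations from
the standard — is standard; a published functional form is not):

* Per table, a **two-point anchor fit**: α, β solved exactly from
  Y(5) and Y(60). Residuals therefore vanish at both anchor
  boundaries for every table, and the fitted correction profiles pass
  smoothly through zero there. (A least-squares per-table fit was
  tried and rejected: it leaves nonzero anchor residuals, and forcing
  the corrections to zero at an anchor afterwards creates a kink
  large enough to break survivorship monotonicity when applied.)
* Deviation covariates z_c = 1 − Y(5)/Ys(5) and z_a = 1 −
  Y(60)/Ys(60). Over a corpus whose dominant variation is the
  mortality level these are nearly collinear (correlation ≈ 0.99), so
  a joint least-squares split of the residuals is unstable.
  Identification is hierarchical: θ is the per-boundary slope on the
  level-orthogonalised part of z_a (the adult-specific deviation),
  γ on what z_c explains of the remainder.
* At prediction, the covariates are evaluated on the first pass
  Y⁰ = α + β·Ys and do not feed back: the corrected schedule is then
  the fixed point of the update map by construction. A feedback
  iteration was tried and diverges whenever |γ(60)·θ(5)| >
  |Ys(5)·Ys(60)|, which realistic calibrations violate.
* **Child-only input case:** the expected adult level is first
  predicted from a companion regression of log10(45q15) on a
  quadratic in log10(5q0) fitted on the calibration corpus, and the
  table is then matched on both anchors. A β = 1 transform with α
  solved from 5q0 was tried and rejected: with anchored corrections
  it cannot follow the empirical adult-vs-child level relationship,
  which distorts both the estimated adult indicators and the
  documented bias directions. Companion equations for the child-only
  case are also how the original implementation of this system
  family is used in practice.

Matching solves the two-indicator cases with a Newton-type 2-D root
(scipy `hybr`) and falls back to nested bisection (outer β, inner α
matched to 5q0); the inner solve is re-polished at the final β so the
5q0 tolerance (1e-9) always holds; e0 is matched to 1e-7 years. The
1-D solvers scan a grid first because parts of the (α, β) axis are
infeasible (corrections can break survivorship monotonicity far from
the standard); the scan brackets the root among feasible points and
bisects toward the feasibility boundary when the root hides in the
sliver between grid and boundary.

## Family/level system

Features for clustering are per-table residual log-rate profiles
after removing a pooled log-quadratic level fit, reduced to their
leading principal components (a full-covariance Gaussian mixture on
all 20 age groups would carry more covariance parameters than tables
per family); the mixture (fixed seed, 5 initialisations, k-means
fallback on degenerate fits) assigns each table to exactly one of K
families (default K = 5). A cluster with fewer than 4 members
triggers a refit at K − 1 with a warning. Families are re-indexed by
mean adult-band residual, so family 0 is always the lowest-adult-
mortality pattern and refits with the same seed are reproducible.

Each family's level model is a per-family (a, b, c) refit on its own
members with k fixed at 0 — one continuous dimension indexed by 5q0.
Level matching for 45q15 or e0 targets is Brent's method on
log10(5q0) over the family's calibration range (expanded by up to
6 × 0.3 decades with a warning before the target is declared out of
range). Family choice from 5q0 alone uses the highest per-family
Gaussian density of member log10(5q0) (ties to the lowest id) — the
original system's rule for this case is not documented, so this is a
stated design choice; with both 5q0 and 45q15 the family minimising
the squared mismatch of its implied 45q15 is chosen. A
nearest-centroid assignment for full tables is also provided.

The 45q15 envelope at a given 5q0 is the min/max of the K families'
implied values; the range diagnostic flags observed (5q0, 45q15)
pairs against it and measures an outside point's relative error
against the nearer bound, 100·|obs − bound|/obs.

## Assessment

Residuals are estimated − observed ("+" = overestimate). ARE is
100·mean(|est − obs|/obs) with zero observations excluded (warned).
Bias classes: all residuals within tolerance → "0"; ≥ 90 % of
above-tolerance residuals one sign → "+" or "−"; otherwise the sign
sequence is 3-point median smoothed, exactly one sign change gives
"−+" or "+−", and anything else falls back to the majority sign. The
90 % threshold and the smoothing are this package's operationalisation
of a by-eye classification.

Trend statistics compound over n − 1 year-to-year intervals:
r solves q1·(1 − r/100)^(n−1) = q2 and is returned as the positive
decline rate; the e0 gain is (e0_end − e0_start)/(n − 1), the same
interval convention applied uniformly. This convention reproduces
every verifiable published decline rate to the printed precision
(within one unit in the last place).

## Synthetic data: what it emulates, and what it does not

The generative truth is a hand-constructed log-quadratic coefficient
set chosen so that (i) rates increase with the 5q0 level at every
age, most responsively in childhood; (ii) 1q0 stays near 0.7–0.8 of
5q0 across the calibration range 0.0025–0.13, keeping the under-five
constraint feasible; (iii) v is a unit-norm adult bump over ages
15–79. The female truth lowers the 15+ baseline by a factor 0.75 —
the usual female survival advantage — so per-sex corpora and series
share one base pattern.

Corpora sample 5q0 log-uniformly (default range 0.0025–0.10,
200 tables), k uniformly in the configured bounds (orthogonalised as
above), optional family deviation profiles (adult-band bumps of
±`spread` in log10, evenly spaced across K families, childhood
untouched), and i.i.d. Gaussian log-rate noise. By default family
patterns vary independently of level; narrower per-family 5q0
windows (ordered with pattern severity) are available as an option.

The China-like observed series interpolates 5q0 geometrically between
the published per-sex endpoints (male 0.03946 → 0.00698, female
0.05280 → 0.00514 over 19 years, so the compound decline statistics
reproduce 9.18 %/12.14 % per year). With the crossover on, the female
path is held at ≥ 1.02× the male path through the penultimate year —
the minimal departure from a pure geometric path compatible with the
published endpoints, since two geometric paths through those
endpoints would cross mid-series — and the generator verifies that
female e0 exceeds male e0 in every year, signalling infeasible
configurations. Adult (15–59) and old-age (60–79) rates are scaled by
0.7 relative to the calibration pattern (females by a further 0.9),
which is what makes every 5q0-level-only estimate overestimate 45q15
and 20q60 and underestimate e0 — the bias structure the assessment
stage is designed to expose. Other-country series use the published
per-country endpoints with no pattern deviation and no crossover.

What passing tests therefore show: the estimators recover their own
generative models exactly, the matching cases reproduce their inputs
at solver tolerance, and the evaluation machinery reads out a known,
constructed bias correctly. What they cannot show: agreement with any
published ARE values for real populations — those depend on the
actual yearbook and HMD schedules, whose age-pattern detail (sampling
error structure, urban/rural composition, old-age data quality) the
generator does not emulate beyond a single noise scale and
multiplicative band deviations.

## Problem sizes

Default study sizes — 250-table calibration corpora per sex, 200-table
noise-free recovery corpora, 19-year series, K = 5 families — run the
full suite in well under a minute and the end-to-end acceptance
recomputation in a few seconds on one core.

## Known limitations

* The modified-logit corrections are a documented variant, not a
  replication of any published correction table; likewise the family
  shapes are corpus-specific, not the published families.
* Single-year (complete) life tables, graduation, and cause-of-death
  structure are out of scope; the HMD reader aggregates single-year
  input onto the abridged grid.
* The family-from-5q0 rule is only as informative as the association
  between level and pattern in the calibration corpus; with fully
  overlapping family level ranges it degenerates to the tie-break.
* e0 gains per year use the same n − 1 convention as the decline
  rates; the published gains cannot be verified without the start and
  end e0 values, so one convention is applied uniformly.
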