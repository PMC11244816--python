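# Methods

## Data model

The analysis unit is the quarterly life table: one contiguous
three-month calendar period with a live-birth count and a deaths matrix
indexed by age band × cause. Four age bands partition the neonatal
period in completed hours — [0, 24), [24, 48), [48, 168), [168, 672] —
chosen to hold comparable numbers of deaths while staying programmatically
meaningful (first day, second day, rest of the first week, weeks 2–4).
Bands are half-open except the last, which closes at 672 h: a death at
exactly 672 completed hours is still neonatal; older deaths are tallied
as post-neonatal and excluded, never silently dropped. Age at death is
the floor of the birth-to-death time difference in hours.

Cumulative mortality is the simple ratio
`q(x,c) = (deaths of cause c at ages ≤ x) / live births`, with no
actuarial exposure correction: the cohort design follows every live
birth for the full 28 days, so the denominator is complete. The
all-cause NMR of a table is `Σ_c q(28d, c)` by construction.

Deaths are assigned to quarters by **date of death**; the denominator is
the quarter's live-birth tally. This is an approximation (a birth late
in one quarter can die early in the next), adopted because the grouping
is defined by when deaths occur while no explicit rule ties denominators
to those groups. The generator produces exactly this structure, and the
aggregator tallies any death falling outside the configured quarter
range rather than dropping it.

Six cause codes are carried: preterm, asphyxia, sepsis, pneumonia,
congenital, and a catch-all `other`. Only the first five are modelled;
`other` (and any unrecognized code, which is pooled into it) contributes
to the all-cause NMR only. Records lacking a death time or a verbal
autopsy are excluded up front; a record missing both counts once, under
the missing-death-time reason, keeping the exclusion tally additive.

## The adapted log-quadratic model

Per cause, and per cumulative age group x:

    log q(x,c) = a(x,c) + b(x,c)·z + c(x,c)·z² + v(x,c)·k,   z = log nmr

**Coefficients.** Unweighted OLS of `log q(x,c)` on `(1, z, z²)` across
training quarters, solved by `numpy.linalg.lstsq`. Identifiability
requires ≥ 4 tables with ≥ 3 distinct NMR values and all NMRs positive;
violations raise a singular-design error naming the offending input.
Any cell with q = 0 is replaced by an offset of 1e-5 before the log.
The offset is applied uniformly to every cause — in practice only the
rarer causes (sepsis, pneumonia, congenital) ever have zero quarterly
cells, so this uniformity changes nothing for the common causes.

**Deviation vector.** The estimation of v is a design choice in the
Lee–Carter/log-quadratic tradition: v is the first right singular
vector of the (quarters × ages) training residual matrix, sign-fixed so
its last entry is positive and rescaled so v(28d) = 1 exactly. A
numerically zero residual matrix (largest singular value < 1e-12)
raises `NoDeviationSignal`; a leading singular vector with |v(28d)| <
1e-8 raises `DegenerateDeviation`, since k would then be
unidentifiable. v is estimated per cause, independently; no joint
estimation across causes is attempted.

**Shape parameter.** Because v(28d) = 1, the k that makes the model
reproduce an observed cause-specific NMR at 28 days is closed-form:
`k = log(cause_nmr) − (a + b·z + c·z²)` evaluated at the last age
(cause_nmr = 0 goes through the same 1e-5 offset). No root finding is
needed, and the 28-day prediction then matches the observation to
floating-point accuracy — this is what produces the exactly-zero
28-day cross-validation errors for the best-k column.

**Predictions** are `exp(·)`, hence strictly positive, and are reported
raw: no monotonicity repair across ages, no truncation, and no
constraint tying the five causes to the all-cause envelope (each cause
is modelled separately). Extreme extrapolations from unstable
small-sample fits may overflow to `inf`; they are reported as such.

## The standard comparator

Constant daily cause-specific mortality: the cumulative prediction at
an age bound of h hours is `cause_nmr · h/672` — linear allocation of
the 28-day risk by elapsed time. A constant-hazard exponential
allocation would differ only at O(q²) for neonatal-scale probabilities
and be equally exact at 28 days; the linear reading is the plain sense
of "average daily rate". The fraction is computed before the
multiplication so the 28-day prediction reproduces `cause_nmr`
bit-exactly.

## Cross-validation

Leave one quarter out: fit on the remaining quarters, predict the
holdout three ways (k = 0; best k; standard). The holdout's observed
all-cause NMR is the covariate and its observed cause-specific NMR
feeds the k-calibration and the baseline: the exercise validates the
estimated **age pattern given the mortality level**, not the level
itself. Absolute errors are averaged over holdouts. Relative errors
average |error|/observed over holdouts with a non-zero observation, and
are reported only for preterm and asphyxia; for the rarer causes the
observed quarterly rates are so often zero that the ratio is not
meaningful, and the output leaves those cells empty. Summary tables are
written to 5 decimal places.

A training fold whose residual matrix is numerically zero (possible
only on exact model surfaces) falls back to v = (0,…,0,1), which
preserves the exact 28-day calibration and perturbs nothing else.

## Synthetic data

`generate_cohort` emulates the structure of a quarterly neonatal
mortality surveillance system with verbal-autopsy cause assignment:

* 25 quarters from 2010Q4, 1,400 births per quarter (defaults);
* all-cause NMR interpolated **log-linearly** between the 35.3 and 27.9
  per-1000 endpoints (only the endpoints are specified; log-linearity
  is the natural choice for a rate trend);
* deaths per quarter ~ Binomial(births, nmr); age band ~ the
  41/15/25/19% distribution; cause ~ a per-band profile with
  prematurity/asphyxia dominating early bands (52/42%, then 55/35%),
  prematurity/asphyxia/sepsis at 38/26/18% in the first week, and
  sepsis leading at 39% (asphyxia 16%) in weeks 2–4. Probability mass
  not assigned to the named leading causes is split equally among the
  remaining causes — a fixture choice, not an empirical claim;
* death time uniform within the band, birth time uniform within the
  quarter (minute resolution), so a small fraction of deaths spill into
  the next calendar quarter — consistent with the death-date quarter
  assignment above;
* missingness: 5% of death times, 0.2% of verbal autopsies, injected
  independently;
* one `numpy` Generator seeded from the single config seed; identical
  configs give byte-identical cohorts.

What the generator does **not** emulate: the within-band shape of the
age distribution (uniform here), cause misclassification by the
verbal-autopsy algorithm, seasonality, or any trial-arm structure.
Passing tests therefore demonstrate correctness of the estimation
machinery and its structural properties under realistic sample sizes —
not that the model fits any particular real population.

`generate_from_model` draws life-table surfaces from the log-quadratic
equation itself (optionally with i.i.d. Gaussian log-scale noise) for
parameter-recovery studies: with 200 quarters at noise sd 0.01 the OLS
recovers the b-coefficients within ±3 standard errors and the deviation
vector with cosine similarity > 0.99 (asserted in the test suite).

## Numerical and design choices

* Zero-cell offset 1e-5, in both fitting and calibration.
* OLS standard errors for b use the per-age residual variance with
  n − 3 degrees of freedom; when the generating process includes a
  random k, the v·k term inflates those residuals, making the ±3 SE
  recovery check conservative.
* The SVD sign convention plus the degeneracy guard make v unique; ties
  are impossible once |v(28d)| ≥ 1e-8.
* Problem sizes in the tests and the acceptance script (25-quarter
  cohorts; 200-quarter recovery studies; 10⁷ births for the generator
  calibration) were chosen so each check has clear statistical
  resolution at desk scale.

## Limitations

* The quarter-of-death denominator approximation above.
* Underlying cause only; multiple-cause VA output is out of scope.
* Cross-validation error on synthetic cohorts characterizes the method
  under the generator's assumptions; real surveillance data add
  measurement error (especially VA cause assignment) that is not
  simulated.
* Rare causes are estimated poorly by design visibility: zero cells
  enter as log(1e-5), which can destabilize their quadratic fits — the
  same behaviour the method exhibits on real sparse data.
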