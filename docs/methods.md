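# Methods

This note documents the statistical model, the defaults and why they
were chosen, the synthetic-data generator's scope, and the numerical
conventions. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Estimands

The package estimates, for a longitudinal pregnancy cohort followed to
delivery:

1. **ANC coverage** — the proportion of women attaining at least
   k = 1, 4, 8 visits during pregnancy, with the per-woman total
   assembled as (self-reported count at enrollment) + (distinct
   prospective chart-visit days on/after enrollment). Retrospective
   chart abstractions never enter totals; they exist to validate
   self-reports.
2. **Retention in care** — sequential retention after window X
   (X = 1..3): among attenders of window X, the share attending any
   later window; cumulative retention through window k (k = 1..4): the
   share of the cohort attending windows 1..k with no gap. The ANC
   windows are <16, 16–<28, 28–<36, and ≥36 weeks GA, half-open.
3. **LTFU sensitivity bounds** — deterministic re-estimates of coverage
   under the assumption that women lost to follow-up attend no more
   than completers (details below).

## Interval estimation

All proportions carry Agresti–Coull intervals at a configurable level
(default 95%). The exact normal quantile (≈1.959964) is used rather
than 1.96; at one-decimal percent rounding both choices agree, which
the test suite verifies against the published tables. Report tables
round percentages to one decimal, ties away from zero; internal values
are never rounded. The interval is clipped to [0, 1] and always
contains the raw proportion x/n (checked exhaustively for n ≤ 200 in
the tests), and its empirical coverage at the study's scale
(n = 150, p ≈ 0.34) is verified by simulation to lie in [0.93, 0.97].

## Gestational-age dating

GA is maintained in integer days (weeks are derived views), which makes
the half-open window boundaries exact: 16 weeks is day 112, and a visit
on day 112 belongs to window 2. The anchor hierarchy is:

1. ultrasound performed before 16 weeks GA — anchor at the scan;
2. LMP when a ≥16-week ultrasound exists and the LMP-implied GA at the
   scan date disagrees by at most `ga.discrepancy_limit_days`;
3. LMP alone when no ultrasound exists;
4. fundal height at the measurement date, 1 cm ≈ 1 week
   (`ga.fundal_height_rule`, overridable);
5. maternal recall, months × 365.25/12 days
   (`ga.recall_days_per_month`).

The discrepancy limit defaults to 10 days — a conventional
second-trimester redating cut; the underlying clinical guidance names
no number, so this is a documented assumption, configurable and
recorded in `run.json`. A late ultrasound whose LMP check fails never
dates the pregnancy itself; the hierarchy falls through to fundal
height or recall, and a record with no usable evidence is routed to the
implausible-GA exclusion bucket rather than silently dropped.

## Exclusion cascade

Exclusions are applied in a fixed order — miscarriage (pregnancy loss
<28 weeks, identified by outcome), implausible documented GA
(enrollment ≤0 or ≥46 weeks, delivery <28 or ≥46 weeks, boundaries
taken literally), then loss to follow-up — so the tally buckets are
disjoint and sum to the input minus the analysis count. Whether LTFU
is counted before or after the GA screen is not externally fixed; this
order reproduces the published arithmetic (the LTFU share is reported
out of the post-GA-screen remainder) and is asserted by a test.
"Followed until delivery" is operationalized as a present delivery date
with outcome live birth or stillbirth; LTFU records must instead carry
a censoring date.

## Visit-count assembly rules

A visit is a day: same-day duplicate chart rows collapse. A
prospective chart visit dated before enrollment is a data error; it is
reassigned to the pre-enrollment pool only when the woman's self-report
count is zero, otherwise dropped with a warning — under the
self-report + prospective combination rule, double counting is the
worse failure mode. Undated pre-enrollment self-reported visits set
only the ANC 1 window flag; this is valid because the retention
analysis runs on the subcohort enrolled before 13 weeks, inside
window 1. The quartile convention for the visit-count median/IQR is
configurable (`rounded_rank`, the sorted-value-at-round(q·(n+1))
convention that yields integer quartiles for integer counts, or
`linear` interpolation); the choice is recorded with the run.

## LTFU scenarios

For ≥1-visit coverage, the single scenario counts a lost woman as
covered only if she had a recorded visit before censoring. For
≥4-visit coverage, a lost woman with v ≥ 4 visits at censoring counts
fully; one with v < 4 contributes f × P̂(total ≥ 4 | total ≥ v), the
conditional estimated empirically among completers with at least v
visits (falling back, with a logged warning, to overall completer
coverage if no completer has ≥ v visits). The attenuation f sweeps
0–0.9 by default. This conditional construction is the most literal
reading of "coverage proportional to completers, given the visits
attended at loss"; its outputs are validated by bracketing and
monotonicity properties (never below treating lost women as
never-attenders, never above treating them as fully covered, monotone
non-decreasing in f, and exactly equal to the primary estimate when no
one is lost) rather than against external numbers, since no per-woman
censoring data are published. The point proportion keeps the exact
expected numerator; the interval is computed on the half-up-rounded
numerator, since Agresti–Coull operates on integer counts. Whether
scenarios run on the early-enrollment subcohort or the full analysis
population is a config switch (`scenario_scope`, default subcohort).

## Group comparability

Continuous covariates are compared between early (<13 weeks) and later
enrollees with Student's t-test; categorical covariates with a
chi-squared test, replaced by Fisher's exact test for 2×2 tables with
any expected cell below 5 (the conventional switching rule; the choice
made per row is recorded in the output). The 2×2 chi-squared uses the
Yates continuity correction: on the published baseline table this
reproduces the printed p-value for the history-of-stillbirth row, which
the uncorrected statistic does not, and the correction is the
conservative default at these cell sizes.

## Synthetic-cohort generator

The generator emulates the features of the real data that the analysis
depends on, with known truth:

- **Enrollment timing** — a mixture: with probability
  `first_trimester_frac` (default 0.072) uniform over 6–13 weeks,
  otherwise uniform over 13–32 weeks.
- **Delivery GA** — normal (default mean 39, SD 2 weeks) truncated to
  [28, 46); a `miscarriage_rate` fraction instead lose the pregnancy
  before 28 weeks, and an `implausible_ga_rate` fraction carry
  corrupted documented GA (enrollment before conception, enrollment
  ≥46 weeks, or delivery ≥46 weeks) to exercise the exclusion screen.
- **Attendance** — a two-state first-order chain over the four windows
  with marginals `window_attendance_probs` (default 0.807, 0.587,
  0.493, 0.290 — the margins implied by the published window
  denominators) and coupling `dropout_persistence` ρ ∈ [0, 1] via
  P(A_k ∧ A_{k+1}) = p_k p_{k+1} + ρ√(p_k q_k p_{k+1} q_{k+1}); ρ = 0
  is independence, and infeasible (marginals, ρ) combinations are
  rejected at construction. First-order dependence is the minimal
  structure able to move marginal attendance and sequential-retention
  drop separately; anything richer is unidentified from published
  margins. Default ρ = 0.3, a mild positive carry-over.
- **Visits** — one visit per attended window, placed uniformly (in
  days) within the window, after day 42 (~6 weeks, the earliest
  plausible first contact) and strictly before delivery. A window is
  attendable only if delivery falls after it opens.
- **Observation processes** — pre-enrollment visits surface only as a
  self-reported count passed through the error process (exact with
  probability `selfreport_exact_prob`, default 0.5, else a uniform
  nonzero error of at most `selfreport_error_spread`, clipped at zero);
  a `retrospective_fraction` of women with pre-enrollment visits also
  get dated retrospective chart rows, feeding the agreement
  assessment; an `ltfu_rate` fraction (default 0.063) are censored at
  a uniform GA between enrollment and delivery with delivery fields
  blanked.
- **Dating evidence** — each woman receives one evidence pattern
  (probabilities in `evidence_probs`) constructed to be exactly
  consistent with her conception clock, so the resolved anchor
  reproduces truth to the day; for maternal-recall women the enrollment
  GA is snapped to the nearest whole recalled month to preserve that
  exactness. GA corruption for implausible records is injected only on
  LMP-dated records, since fundal-height and recall anchors cannot
  encode a negative GA.
- **Covariates** are drawn independently of the visit process, with
  marginals near the published baseline table; the generator makes no
  attempt to model facility choice, covariate effects on attendance, or
  seasonality.

Randomness: one `numpy` Generator per woman, seeded
`default_rng([seed, i])`, so identical (config, seed) gives
byte-identical tables and extending the cohort does not perturb
existing women.

`implied_truth` returns the chain's closed-form expectations (window
marginals, P(≥1 visit), cumulative retention), ignoring delivery
truncation. Parameter-recovery tests therefore use a delivery
distribution concentrated at term (mean 39.5, SD 1.0 weeks), under
which the probability of delivering before window 4 opens is ~2×10⁻⁴
and truncation bias is negligible against 3 Monte-Carlo SE; recovery
runs use n = 20,000 women, large enough that 3 SE is under one
percentage point for every recovered quantity while the whole suite
stays fast. Passing recovery tests show the estimators are consistent
for the generator's process — not that real cohorts satisfy that
process; in particular the generator has exactly one visit per window,
independent covariates, and noiseless dating evidence, all of which
real data violate.

## Known limitations

- The self-report error model is symmetric and memoryless; real recall
  error likely depends on the true count and on enrollment GA.
- The generator cannot produce more than four true visits per
  pregnancy, so the upper tail of the visit distribution (and any
  eight-visit coverage above zero) is out of its range by design.
- Fisher's exact substitution applies only to 2×2 tables; sparse
  larger tables fall back to chi-squared with a per-row note.
- No regression modeling of coverage determinants, stratified
  retention, imputation, or inverse-probability weighting for LTFU:
  the scenario bounds are the intended sensitivity machinery.
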