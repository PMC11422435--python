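# Methods

This note documents the models, conventions and design choices behind
`rocftrace`, in the spirit of a statistical methods appendix. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Figure scoring

Each ROCF performance is scored over 18 structural units, 0–2 points in
half-point steps (36 maximum). All arithmetic is carried out in integer
half-points internally, so sums are exact and no floating-point drift
can accumulate; values are rendered as decimals on output.

**Unit partition.** Lateralised scoring needs a left/right assignment
of the 18 units with maxima of 12 (left) and 16 (right) points. The
instrument's published description fixes only those maxima, not the
unit numbers, so the default partition is a documented choice derived
from the standard Osterrieth unit layout:

- left (6 units, max 12): 1, 6, 7, 8, 17, 18 — upper-left cross, left
  small rectangle and its details, lower-left elements;
- right (8 units, max 16): 9–16 — the right-attached triangle complex
  and right-field details;
- midline (4 units, unscored laterally): 2–5 — the large rectangle and
  its diagonals and medians.

Every scoring operation takes the partition as a parameter and a
different assignment can be supplied as JSON/YAML
(`{"left": [...], "right": [...], "unassigned": [...]}`); the
constructor enforces disjointness, coverage and the (12, 16) maxima.

**Laterality Index.** LI = (left/12)/(right/16). When the right score
is 0 the ratio is undefined; the package returns NaN rather than
infinity, and all downstream statistics exclude NaNs with a logged
per-group count. LI is scale-invariant in the two lateral proportions
and weakly monotone in each unit score (increasing a left unit can only
raise it, a right unit only lower it); both properties are exercised in
the test suite.

**Overlapping scores.** Per unit, 1 point per complete re-trace plus
0.5 per incomplete re-trace; side scores sum over that side's units and
the total over all 18. Midline-unit overlaps therefore count toward the
total but toward neither side — the published description defines the
total over all scored units and the worked example (1.0 + 1.5 = 2.5) is
consistent with either reading, so the more inclusive one was chosen
and is asserted in tests.

## Screening classification

A right-brain-damaged patient is USN+ if **any** of four tests flags:
left-minus-right line-cancellation omissions ≥ 2; star-cancellation
score below cutoff; rightward line-bisection deviation at or beyond
cutoff; at least one omitted left-side landscape detail. The
star-cancellation (< 51 of 54) and line-bisection (≥ 8.5% of line
length, rightward positive) cutoffs are *documented placeholders* for
the Behavioural Inattention Test's standardised values, which the
instrument's licensees publish; deployments should confirm them in the
cutoff config, including the bisection unit tag (`percent` or `mm`).

The bisection deviation is stored as a signed scalar, positive toward
the right, and flagged at `deviation >= cutoff`; consequently its ROC
orientation is "higher indicates USN". Published ROC tables sometimes
print bisection cutoffs with a `<` inequality because they analyse a
score rather than a deviation; the direction convention here is fixed
and declared per measure, so either encoding can be reproduced by
flipping the orientation.

## Group statistics

Bounded, heavily tied half-point scores are not plausibly normal, so
the pipeline records a Shapiro–Wilk routing decision per measure
(α = 0.05, zero-variance groups routed nonparametric with a warning)
but implements only the nonparametric branch: Kruskal–Wallis omnibus,
the three pairwise Mann–Whitney tests, Holm step-down adjustment over
the three p-values. Pairwise p-values are exact (full permutation
distribution) when both groups have n ≤ 8 and no ties, asymptotic with
mid-ranks and tie-corrected variance otherwise.

**Effect size.** The literal formula r = √(t²/(t²+df)) is exposed for
t-type statistics, but the pairwise tests here are Mann–Whitney, so the
default effect size is r = |z|/√N with z the tie-corrected normal
approximation of U (no continuity correction). Which convention a
given published table used is generally not recoverable; both are
available and the choice is documented rather than hidden.

**Correlation screen.** Spearman's ρ between each tracing-task measure
and each conventional measure, pairwise-complete, with a clinical
meaningfulness bar of |ρ| > 0.8 — deliberately high because with n = 20
moderate rank correlations arise by chance.

**Demographics.** Continuous variables: median (Q1–Q3) per group with
Kruskal–Wallis (3 groups) or Mann–Whitney (2 groups; e.g. stroke-onset
fields observed only in patients). Categorical variables: counts with
Fisher's exact test. For tables larger than 2×2 no installed library
offers an exact r×c test, so a small exact enumerator over all tables
with the observed margins (network algorithm, two-sided by summing
probabilities ≤ the observed table's) is included; it reduces to the
scipy 2×2 result and is guarded against combinatorial blow-up.

## ROC analysis

Each measure carries an explicit orientation (scores and LIs: lower
indicates USN; overlapping scores and bisection deviation: higher).
AUC is the Mann–Whitney kernel mean — P(case beyond control) + 0.5
P(tie) — and its 95% CI uses DeLong's structural-components variance
with a normal approximation, truncated to [0, 1]; perfect separation
collapses the CI to the point estimate with a warning. The reported
cutoff is the midpoint between adjacent observed values whose operating
point minimises the Euclidean distance to (sensitivity, specificity) =
(1, 1), with deterministic tie-breaks (higher sensitivity, then higher
specificity, then the smaller cutoff); values equal to the cutoff count
as on the USN side. "Percent beyond cutoff" uses all patients (both
classes) as the denominator — the natural reading for a screening
yield, made explicit because published tables rarely state it.
Accuracy bands: AUC ≥ 0.9 high, ≥ 0.7 moderate, > 0.5 rather
inaccurate, ≤ 0.5 chance (boundaries to the higher band).

## Synthetic cohorts and calibration

The original study's per-subject data are unavailable, so the
generator emulates three cohorts whose *derived-measure medians* match
the published group summaries (figure scores, LIs, overlapping scores
per task; healthy 40, USN− 10, USN+ 10 by default).

**Family.** Unit correctness is i.i.d. per unit within a side, drawn
from a categorical distribution over {0, 0.5, 1, 1.5, 2} parameterised
as Binomial(4, p)/2 with a side-, group- and task-specific p (midline
tied to the right-side p). Overlap counts are Poisson per unit with
complete:incomplete count rates in a fixed 1:2 ratio (so each
contributes half the expected points). Screening results are drawn so
USN− and healthy subjects pass every battery rule while each USN+
subject draws a random non-empty subset of the four deficits
(probabilities 0.40/0.45/0.50/0.40), keeping per-test sensitivities
moderate while the any-test rule always fires; if clipping leaves no
flag set, a single landscape omission is imposed, because the battery
*defines* group membership. Agreement between generated screening and
generating group is asserted at generation time.

**Calibration.** Under this family the left and right half-point
scores are Binomial(24, p_left) and Binomial(32, p_right), so the
distribution of LI is an exactly computable function on a 25×33 grid
and score totals follow from convolutions; overlap totals are
Poisson-convolution distributions on a half-point grid. Calibration is
therefore a coarse-to-fine grid search over (p_left, p_right) per group
and task minimising |median LI − target| + 0.02·|median total − target|
with *exact* 0.5-quantiles (a noiseless version of simulated quantile
matching), and a one-dimensional scan for the overlap scale matching
the total-overlap median with side rates in the targets' left:right
proportion. Achieved-vs-target medians are stored in
`config.calibration_report`; infeasible targets (e.g. an LI median
impossible under the score maxima) raise a named error.

Two compromises are inherent and documented: (i) medians are not
additive, so when the side-overlap targets sum above the total target
(as in the USN+ tracing group) the total median is matched exactly and
the side medians land slightly below their printed values; (ii) the
total-overlap scale is half-point discrete, so a printed median that is
an average of order statistics (3.25) is matched to within a
quarter-point.

**What the generator does and does not emulate.** It reproduces group
medians of the derived measures and qualitative screening behaviour; it
does **not** model within-subject correlation between tasks, spatial
structure across neighbouring units, rater behaviour, or the full
spread (IQRs are implied by the family, not fitted). Consequently the
between-group *separability* of measures — and hence sampled AUCs,
sensitivities and correlation magnitudes at n = 10 per patient group —
varies around the published values rather than reproducing them;
passing tests demonstrate the pipeline's correctness and the stated
median recovery, not clinical performance on real patients.

**Problem sizes.** The calibrated-recovery checks use 200 subjects per
group (median standard error ≈ 0.01 LI units under the family, an
order of magnitude below the ±0.05 tolerance); integration tests use
reduced cohorts of 6–12 per group; the DeLong coverage check uses 500
replicates at n = 10 + 10.

## Numerical conventions

- Score arithmetic in integer half-points; equality comparisons on
  scores are exact.
- Discrete medians use the lower 0.5-quantile during calibration and
  numpy's midpoint convention on samples; at the calibrated parameters
  the two agree to within the half-point grid.
- Holm adjustment via statsmodels, verified against a hand step-down
  oracle.
- The pipeline's outputs contain no timestamps; a rerun on identical
  inputs is byte-identical, and each run directory records the seed and
  a SHA-256 hash of the effective configuration.

## Known limitations

- The default unit partition is a constrained reconstruction, not the
  original authors' list; analyses sensitive to single-unit assignment
  should supply their own partition config.
- The screening cutoffs ship as placeholders for the standardised
  battery values and must be confirmed per deployment.
- The generator's independence assumptions make the synthetic ROC
  tables illustrative rather than confirmatory.
- No parametric comparison branch, no recall/delayed-memory task
  conditions, and no image-level scoring of drawings: the package
  consumes unit scores assigned by a trained rater.
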