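# Methods

This note documents the statistical conventions, the synthetic-data
model, the numerical choices, and the known limitations of `dmcreport`.

## Data model and conventions

All tables are subject-level pandas DataFrames shaped like the CDISC
ADaM safety datasets (ADSL/ADAE/ADLB/ADEX analogues). Time is expressed
in *study days* under the CDISC convention: day 1 is the day of first
dose, there is no day 0, days before first dose are negative. Readers
accept either precomputed `*_day` columns or ISO-8601 dates converted
against a per-subject first-dose date; a precomputed day column wins if
both are present. XPT (SAS transport v5) input is read-only through
`pandas.read_sas`; CSV is the canonical round-trip dialect.

Arms are declared as an ordered list with the reference (control) arm
last, which is also the display order (control below/after treatment in
every figure). A data cutoff drops records starting after the cutoff
day and truncates intervals running past it; `assemble_trial` is
idempotent under a fixed cutoff.

## Adverse-event statistics

**Safety population and treatment emergence.** The denominator of every
incidence is the dosed population of the arm. An event is treatment
emergent if its onset lies in `[first dose day, last dose day + lag]`
with a configurable lag defaulting to 30 days; which window to use is
ultimately a protocol decision, and 30 days is a common follow-up
convention.

**Person-time.** Per subject, exposure runs from first to last dose day
inclusive, divided by 365.25. For exposure-adjusted rates, person-time
can optionally be truncated at the subject's first event of the term
(time-at-risk semantics); the default keeps the simpler full-exposure
denominator so that the overview display stays easy to read.

**Exact test.** The per-term p-value is the two-sided Fisher exact test
on the subject-level 2×2 incidence table, computed by direct
enumeration of the conditional hypergeometric distribution. Two-sided
is defined by the minimum-likelihood rule: sum the probabilities of all
tables (same margins) whose point probability is at most the observed
one, with a relative tolerance of 1e-7 so that mathematically tied
masses computed in log space are not lost to rounding. The enumeration
sums masses with exactly-rounded `math.fsum`, which makes the p-value
bit-for-bit invariant under swapping the compared arms. The all-zero
table has no defined test and returns missing. A Cox or stratified
model is deliberately out of scope: in a screening display over dozens
of terms, the exact test is robust at small counts and requires no
asymptotics, and the p-values are explicitly descriptive.

**Effect scales.** The volcano's x-axis is the risk difference in
percentage points (linear axis, null line at 0) or the exposure-
adjusted incidence rate ratio (log axis, null line at 1). The rate
ratio applies a continuity correction `c = 0.5` to both numerators only
when either event count is zero, which keeps the estimate finite and
preserves exact inversion symmetry between the two arm orderings. A
hazard-ratio axis would require a time-to-event fit per term; the rate
ratio is the descriptive stand-in and every caption labels it as such.

**Multiplicity.** Benjamini–Hochberg is applied once across all
preferred terms of one arm-pair comparison; different comparisons are
separate families. Note that the BH step-up transform is *not*
idempotent: re-adjusting adjusted values multiplies by `m/rank` again,
and only constant vectors are fixed points (for example
`[0.27, 0.041, 0.017, 0.813, 0.913]` adjusts to
`[0.45, 0.1025, 0.085, 0.913, 0.913]`, which re-adjusts to
`[0.75, 0.25625, 0.25625, 0.913, 0.913]`). Adjusted values are computed
from raw p-values exactly once.

**Term ordering.** The overview dot plot orders terms by the chosen
arm's incidence, ties broken by the other arms' incidence, then
alphabetically — a deterministic total order, so re-renders are stable.

## Laboratory derivations

**Limits of normal are per measurement.** Reference ranges routinely
differ by subject (age, sex, laboratory), so every flagging and grading
decision uses the limits carried on the record itself. Reference lines
in figures are drawn only when the limits are common to all subjects
shown; otherwise they are suppressed and the caption says so.

**Boundary convention.** Abnormal requires a strict inequality: a value
exactly at the ULN is normal, exactly at a grade threshold is the lower
grade. The convention is configurable (`strict=False` flips it) and
stated here because shift tables and prevalence plots visibly depend on
it. A missing limit makes a flag `unknown` only when the decision
actually depends on that limit; unknown-flag measurements are excluded
from both numerator and denominator of prevalence but retained in
distribution plots.

**CTC grading.** Grades 1–4 are defined by four strictly monotone
thresholds per parameter, as multiples of the subject's ULN (direction
high) or LLN (direction low), or absolute values. The shipped defaults
(e.g. CK high at 1.0/2.5/5.0/10.0 × ULN) are illustrative configuration
data for the synthetic fixture parameters, not clinical authority;
protocol-approved thresholds must replace them for real use.

**Box statistics.** Quartiles use linear interpolation between order
statistics (`h = (n−1)q`), the common default in scientific software;
whiskers extend to the last data point within 1.5×IQR beyond the box,
and points beyond are listed individually. Because all of these are
order statistics, a log-scaled display only transforms the axis.
Visits with no evaluable value still produce an `n = 0` record so the
per-visit n annotation row stays complete as drop-out thins the sample.

**Shift pairs.** Eligible subjects have a baseline value (the
baseline-flagged record, else the last value on or before first dose;
never-dosed subjects have no baseline) and at least one later value.
The post-baseline value is the worst case by default (maximum for
direction-high parameters, minimum for low) — for a safety audience the
worst excursion is the relevant one — with `last_value` available since
the alternative reading is equally defensible. The classic 3×3 shift
table is rebuilt from the same pairs that feed the scatter, so figure
and table cannot disagree.

**Trajectory selection.** A subject enters the spaghetti display when
any post-baseline value strictly exceeds `multiplier ×` their own ULN
(default 3) or reaches a configured grade (default ≥ 3); each selection
carries its trigger reason.

## Patient profiles

Selection is the union of subjects with a serious AE, a grade ≥ 3 AE,
or a grade ≥ 3 laboratory value, each with reasons. The profile's lab
block is relevance-filtered to parameters that went abnormal for that
subject, showing baseline, worst (by graded direction), worst grade and
last value. The timeline merges the exposure interval, AE intervals
(unresolved ones run to the data cutoff with an ongoing marker), conmed
intervals and abnormal lab values as point events, ordered by day then
track then label. History and conmed lists truncate to the most recent
15 entries with an explicit `+k more` marker to keep a profile on one
page.

## Report assembly

One intermediate representation (sections of text lines, figure specs
and tables) renders to hyperlinked HTML with an anchor TOC and to
paginated plain text with computed page numbers (50 lines per page, one
footer line each; every section and profile starts a fresh page). The
TOC lists the page each section actually starts on; the integrity tests
parse the rendered document and compare. Empty inputs produce explicit
"no events" sentences, never silently missing sections. Arm labels
appear verbatim by default (a DMC report is unblinded); a config flag
relabels arms to `Arm A/B/…` for semi-blinded distribution. The
efficacy section is a placeholder that renders config-supplied text
with a note that interim-look multiplicity handling belongs in the DMC
charter; no efficacy statistics are computed.

The manifest records sections, artifact input hashes, and the subject /
AE / lab-outlier / profile inventories; `diff_since_previous` compares
two manifests to render the "what changed since the previous DMC"
paragraph into the front matter.

**Determinism.** Everything is reproducible byte for byte: generator
streams derive from one seed, figure SVGs use a fixed hash salt and no
timestamps, manifests are sorted JSON, and the exact test is
enumeration-order invariant.

## Synthetic-trial generator

The generator emulates the shape of a two-to-three-arm late-phase
safety dataset. Per subject: age from a truncated normal (default mean
75, sd 8, bounds [18, 90] — an elderly population), sex per arm-level
probability, enrollment uniform over a window (default 90 days),
exposure duration exponential (default mean 150 days) truncated at the
administrative study length (default 182 days), and a dropout fraction
(default 25% in the canned fixture) with shortened exposure.

Adverse events follow a constant-hazard exponential time-to-first-event
model per term and arm; an event is emitted only if it falls within the
subject's exposure. Grade, seriousness and relatedness are drawn from
per-term probabilities. Labs are lognormal with subject-level baseline,
arm-and-visit drift on the log scale, within-subject noise, and
subject-specific limits of normal jittered by a common multiplicative
factor (so LLN < ULN always holds). Outliers are injected at
`outlier_multiplier × ` the subject's own ULN (default 3.5) at
post-baseline visits with a small probability, giving the 3×ULN
selection rule an exact ground truth; the baseline/noise scales are set
so that natural values essentially never cross 3×ULN (≥ 6 sd away on
the log scale).

One independent random stream per output table is split from the master
seed, so adding a lab parameter to a config does not perturb the
adverse-event draws — important for regression-test stability.

What the generator does **not** emulate: realistic MedDRA vocabularies,
correlated multi-parameter physiology, recurrent events (first event
per term only), visit-window noise, or missingness mechanisms beyond
drop-out. Passing tests on synthetic data therefore demonstrate the
correctness of the derivations and the report machinery, not the
clinical realism of any particular display.

## Problem sizes used in the test suite

The canned fixture runs 84 + 86 subjects over a 26-week schedule. The
repeated-seed properties use a scaled companion config (40 subjects per
arm, four AE models, two lab parameters) so that 50–100 replicate
generations complete in seconds; the injected-signal recovery study
uses 200 subjects per arm with one elevated term (hazards 0.15 vs 0.05
per year) among ten background terms at 0.10 per year and a fixed
one-year exposure.

## Known limitations

* No confidence intervals on the volcano axes, no stratified or
  covariate-adjusted comparisons, no recurrent-event or time-to-event
  models — the displays are deliberately descriptive.
* No unit conversion between laboratory unit systems and no
  reference-range imputation; records with missing limits simply drop
  out of flagging.
* MedDRA terms are taken as given strings; no dictionary handling or
  SOC/PT hierarchy rollups beyond the grouping column present in the
  data.
* The paginated text rendering approximates print pagination by line
  count; the HTML rendering uses anchors rather than physical pages.
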