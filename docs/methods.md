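# Methods

## Study design being reproduced

The pipeline implements a cross-sectional disproportionality analysis of
spontaneous reports of suspected serious adverse drug reactions (SADR) in
children aged 0–12 years. The unit of analysis is the individual case
safety report (ICSR): one patient, one or more suspected drugs (ATC-coded,
with pharmaceutical form, route and ICD indication), one or more
adverse-event terms (WHO-ART-style, grouped by system organ class), one
seriousness outcome, and demographic fields. Reports classified as *not
serious* are excluded before any analysis; children above the 12th birthday
are excluded, not clamped.

## Age handling

Age is the calendar-day difference between the event-onset date and the
birth date; when an explicit age field and a date pair disagree, the
date-derived value wins and the discrepancy is logged. Completed years are
anniversary-based. The published age-band labels ("1–3", "3–5", …) overlap
at their endpoints; the only convention that makes them a partition is
half-open-left intervals with the last band closed at the 12th birthday,
and that is what is implemented: baby [0,1), toddler [1,3), preschool
[3,5), primary school [5,8), secondary school [8,12]. Whether the source
bands included the first-birthday day in "0–1" cannot be determined from
the published text; the half-open choice is a recorded design decision, not
an inference. An age of exactly 12 completed years is in-window only on the
anniversary day itself, which is decidable only when dates are present;
from a bare day count, 12 years is treated as out of range.

## Label classification

Off-label classification is **by age only** (dose-, route- and
indication-based off-label use is out of scope). Against a label registry
(drug → licensed flag, approved age interval in days, labelled ADR terms):
absent or unlicensed → `unlicensed`; licensed without a recorded age
interval → `unknown`; otherwise `on_label`/`off_label` by interval
membership. `unknown` is kept distinct from `on_label` so coverage is
honest, but counts as *not off-label* in association tables (conservative
toward the off-label shares), with the tally logged. Event-term matching
against the label is exact on normalized strings; the registry must share
the vocabulary of the events file. Combination products (e.g.
imipenem/cilastatin) are a single entity matched by exact name.

## Disproportionality screen

Tables are case-level: a case contributes at most 1 to each cell regardless
of repeated entries. The denominator N is the set of serious, in-window
cases after preprocessing. Pairs are enumerated wherever `a ≥ 1` but scored
and reported only at `a ≥ 3`, split into strata `3 ≤ a < 5` and `a ≥ 5`.

The published method defines the ROR and its sentinel but not the interval
formula; **Woolf's log-normal interval** with z = 1.959964 is used as the
standard pharmacovigilance choice. `c = 0` yields the sentinel 99.9 with no
interval (sentinel pairs remain SDR-eligible but are flagged distinctly);
`b = 0` or `d = 0` triggers the Haldane +0.5 correction on all four cells,
flagged in the output. The signal boundary `ci_lower > 1` is strict and
evaluated on the unrounded value. The SDR rule is read conjunctively: the
IME-membership condition applies to additionally-monitored drugs as well,
the monitoring list lowering only the case-count threshold (3 vs 5).

## Association tests

Plain Pearson chi-square without continuity correction and without
small-cell exclusion — the reproduced analyses include rows with totals as
small as 3, so the original evidently ran the unadjusted test. The minimum
expected count is reported and a warning is logged when it is below 5; the
statistic itself is never altered. Computation is delegated to
`scipy.stats.chi2_contingency(correction=False)`; tests validate it against
hand-evaluated Σ(O−E)²/E values. The off-label × seriousness table counts
drug entries, not cases.

## Synthetic data generator

The generator emulates the structure of a national pediatric serious-ADR
extract; its defaults are the study conditions:

| parameter | default | basis |
|---|---|---|
| n_reports | 1977 | reported serious in-window case count |
| drugs/report distribution on 1..6 | (0.895, 0.09, 0.01, 0.003, 0.0015, 0.0005) | mean 1.1275 ⇒ ≈2229 drug entries |
| age-group probabilities | (542, 345, 281, 267, 542)/1977 | published age marginals |
| seriousness probabilities | (75, 216, 263, 3, 27, 1393)/1977 | published seriousness marginals |
| gender | 54% male, 1% missing | published shares |
| route/form | 69% IV, 9.3% tablet, 4.5%/3.7% oral sol./susp., 9.6% indeterminate | published shares |
| drug catalog | 33 drugs; ATC level-1 weights ≈ (J 47%, N 17.2%, L 10%, A 6.9%, …) | published ATC profile |
| label registry | synthetic age bounds giving ≈25% off-label, ≈0.5% unlicensed entries | published OL/UL shares |
| injected signals | 11 pairs, λ ∈ [3, 80] | echoing the magnitude range of published signal tables |

Cases are sampled stage-wise from a single seeded stream in a documented
order (age → dates → drugs → events → seriousness → demographics/
missingness), so a fixed seed gives byte-identical CSV output. Ages are
drawn uniformly in day ranges chosen strictly inside each group's possible
anniversary span (e.g. toddler 366–1094 days), so the calendar classifier
always recovers the sampled group regardless of leap days; event dates are
uniform over 2008–2013 and birth dates follow by subtraction, keeping the
age-derivation path exercised.

Event generation is odds-multiplicative: each catalog event occurs with
probability p where odds(p) = background odds × λ if a sampled drug forms
an injected pair with it (λ of several matching pairs multiply). The
expected ROR of an injected pair is therefore ≈ λ, but only approximately:
the rule that a case with no sampled event gets one event resampled from
the background distribution (every report must report something) adds
drug-independent event mass and attenuates observed RORs toward 1. The
effect is negligible when little probability mass sits on empty cases (the
recovery tests use such configs) and modest but visible in the default
calibration, where injected pairs are still recovered. Marginal drug
probabilities act as selection weights for sampling without replacement;
with one drug per report — the dominant case — a weight equals the
per-report marginal.

Deliberate simplifications, hence what passing tests do *not* show about
real data: seriousness is sampled independently of drugs, events and age
(no joint model is asserted by the source — association tests on synthetic
nulls are expected non-significant, which is itself tested);
pharmaceutical form is independent of the drug; there are no reporting
delays, duplicate submissions, drug–drug interactions or secular trends;
vocabularies are simplified controlled lists, not full WHO-ART/MedDRA/ICD
hierarchies.

## Numerical and calibration choices

* Confidence level 0.95 throughout; z from the normal quantile, not 1.96
  rounded.
* Interval-calibration checks draw null 2×2 tables by fixing both margins
  (N = 2000, drug margin 400, event margin 300) and sampling `a`
  hypergeometrically — the exact conditional null of an odds ratio of 1 —
  with margins large enough that Woolf's asymptotic interval is in its
  validity range.
* Signal-recovery checks run 50 replicates of 20,000 reports per
  multiplier; detection-monotonicity checks use 2,000 reports so the λ = 2
  detection rate is informative. Null calibration of the chi-square test
  uses 500 replicate databases at the default size. These sizes were chosen
  to make Monte-Carlo error small relative to the asserted tolerances.
* Degenerate inputs: all-zero rows/columns raise a degenerate-table error
  (helpers can drop empty margins first); pairs with a = 0 are never
  scored; empty databases raise explicit errors rather than returning
  empty summaries.

## Known limitations

The screen implements a single disproportionality statistic (no PRR,
IC/BCPNN, EBGM, shrinkage or age-stratified RORs) and no duplicate-case
detection or causality assessment. An SDR is a statistical flag on
reporting patterns, not evidence of causation, and masking by heavily
reported drugs is not corrected for. The synthetic generator supports
validation of the machinery; absolute signal counts from it do not transfer
to any real database.
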