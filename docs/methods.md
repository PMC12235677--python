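# Methods

This note documents the models, conventions and design choices behind
`glaucobench`, in the order the pipeline applies them.

## Clinical data model

One row per eye-visit: mean deviation (MD, dB) from Humphrey SITA Fast 24-2
perimetry, the false-positive reliability index (%), IOP (mmHg), visual
acuity (Snellen decimal or an off-chart category), and the medication
count; patient-level fields (sex, birth date, diagnosis, risk-factor flags,
procedure events, status dates) are repeated per row.  Dates are ISO-8601
calendar dates, and follow-up time is measured in fractional years
(days/365.25).  MD values are validated against an instrument-scale
plausibility window of [−35, +5] dB; perimeters do not report reliable MDs
outside that range, but the exact floor is a package decision, not a
published constant.  Validation never mutates input; rejected rows are
collected with their row index and reason.

Visual acuity converts to ETDRS letters with the logMAR-chart relation
`letters = 85 + 50·log10(Snellen fraction)`, rounded half away from zero
and clipped to [0, 100].  Off-chart vision maps to fixed letter scores
(finger counting 3, hand movement 2, light perception 1).  Base-10 is the
ophthalmic convention for this formula; the rounding rule is a package
decision since only the formula is conventionally stated.

## Eligibility and attrition

Selection mirrors routine-care cohort construction:

1. **Age**: patients younger than 18 years at onset are excluded.
2. **Reliability**: visual fields with false-positive responses ≥15%
   (inclusive threshold) are removed individually; a patient is excluded
   only when this empties their onset-year fields.  The per-VF rule is a
   package decision — clinic reports state patient-level exclusion counts
   without publishing the per-field rule.
3. **Follow-up span**: a patient is analysed when they retain ≥2 reliable
   fields with at least one in the onset calendar year and at least one in
   or after the final follow-up year (default onset+5).  This operationalises
   "5 years of VF follow-up" as a calendar-year span predicate; published
   cohorts state the resulting counts, not the predicate.

The attrition ledger reconciles the onset population against the analysed
subset.  The deceased count is an *input* (clinics estimate it from an
external mortality-registry rate); the ledger derives
`available = total − no_diagnosis − lost_or_unfit − deceased` and
`not_visited = available − analysed`, and exposes percentages against both
the available and the with-baseline-VF denominators, because both are used
in practice.  All printed percentages are integers rounded half away from
zero.

## Progression

**Rate.**  The per-eye worsening rate is the negated ordinary-least-squares
slope of MD on time in years, so a declining field reads as a positive
dB/year loss.  OLS trend on MD is the standard summary used by the
published real-world comparator studies; the slope is computed from
centered sums (numerically equivalent to the normal equations to ~1e-12).
At least two visits on distinct dates are required.

**Bins.**  Rates classify as slow (<0.5), medium (0.5–1.5, closed on both
ends) and fast (>1.5 dB/year); improving eyes fall in "slow" since the
three-bin scheme has no improvement class.  Baseline severity uses five
continuous half-open bands cut at −2/−6/−12/−18 dB with the cut value
belonging to the worse band (printed band edges like "−5.9" reflect
one-decimal rounding, not gaps).  Age bins are <50, 50–59, 60–69, 70–79,
≥80 years and IOP bins <15, 15–19, 20–24, 25–29, ≥30 mmHg, both as
half-open `[lower, upper)` intervals so non-integer values are covered.
The IOP bin of an eye uses the per-eye reading attached to the baseline
visit.

**Better/worse designation.**  Each two-eyed patient's eyes are compared on
a statistic chosen by method: the onset-year MD (default), the mean MD over
follow-up, or — for the alternating-eyes sensitivity analysis — the mean MD
over visit dates shared by both eyes, which averages out visits where the
eyes swap order.  When the statistics differ by ≥1 dB the higher (less
negative) eye is "better"; below 1 dB the designation is a fair coin from
the seeded generator, so runs are reproducible.  The baseline visit is the
first reliable field of the onset year; within a same-day tie the right eye
comes first, matching perimetry testing order.

## Benchmark report

The report is a versioned schema (`aces-rwm-proto-1`) of per-year
distributions: age, sex, diagnosis, acuity bands (Snellen <0.3 / 0.3–0.5 /
>0.5 computed on the better-seeing eye unless an eye rule filters first),
IOP bins, baseline-severity bins, rate bins pooled and per designation,
clinical progression labels (yes/no/cannot-be-assessed/no-prior-tests —
emitted as not-recorded unless the site supplies counts), treatments, and
cost per patient-year.  Percentages are carried at one decimal internally
and rendered as integers.  Treatment categories are made mutually
exclusive by highest intensity (surgery > laser > medication > none) so
the distribution sums to 100 like every other section.  Quality-of-life
fields are reserved in the schema but never computed, as no instrument is
defined for them.

Small-cell suppression masks any cell whose underlying count is strictly
between 0 and `min_cell` (default 5, a common statistical-disclosure
floor; the governing aggregated-data rule names no numeric threshold).
Masking leaves totals and other cells untouched and is idempotent.
Filters are conjunctive across clauses (eye rule, risk factors, diagnoses,
minimum acuity, severity/age/IOP group subsets, treatments); within the
treatment clause any listed treatment or procedure subtype qualifies.
Comparison documents align shared sections, print signed and absolute
percentage differences, flag one-sided sections "NR", and refuse mixed
schema versions.

## Statistical tests

Wilcoxon signed-rank (zero differences dropped; exact null for ≤25
untied pairs, normal approximation with tie correction otherwise),
Kruskal-Wallis with tie correction against the chi-square reference, and
Pearson chi-square without continuity correction.  These delegate to
scipy.stats; the test suite checks them against independent oracles
(exhaustive sign-assignment enumeration, hand rank computation,
Σ(O−E)²/E).  For left-vs-right median MD the pairing unit (patient or
field) is the caller's choice of inputs; the package does not decide it
silently.

## Synthetic cohort generator

The generator emulates the structure of a routine-care clinic cohort
followed from a fixed onset year, with ground truth returned for recovery
testing.  Defaults, with sources of the choice:

| Parameter | Default | Why |
|---|---|---|
| age at onset | N(68, 11²) truncated [18, 99] | clinic baseline table |
| female fraction | 0.64 | clinic baseline table |
| diagnosis mix | clinic percentages, normalized | printed mix sums to 101.1 due to rounding |
| baseline MD mixture | group weights (0.40, 0.33, 0.17, 0.07, 0.03), uniform within bands (+2..−2, −2..−6, −6..−12, −12..−18, −18..−28) | calibrated so the overall median sits near −3 dB, matching reported medians (−2.9 overall) |
| inter-eye MD correlation | 0.5 via a shared patient-level Gaussian-copula component | similar better/worse distributions are reported but no correlation value; 0.5 is a realistic middle ground |
| rate mixture (slow/medium/fast) | (0.77, 0.17, 0.06) | reported rate-bin proportions |
| per-class slopes | slow N(0.1, 0.15²) clipped to [−0.3, 0.45]; medium U(0.5, 1.5); fast 1.5 + Exp(0.5) | medians near reported per-class rates; clip keeps improvement modest |
| age coefficient | 0.0 dB/year per decade (off) | the mixture then recovers exactly; enable >0 to reproduce the age–progression association |
| measurement noise | Gaussian, SD 1.0 dB | typical SITA test-retest variability |
| instrument floor | −30 dB, applied to measurements, not true state | reproduces the floor-effect attenuation in advanced eyes |
| visit schedule | years {0, 2, 4, 5} | 2-yearly recall plus the final-year visit |
| annual death / no-show | 0.04 / 0.02 | registry-derived clinic estimates |
| procedures | laser 10%, surgery 8% | reported procedure proportions |

**Attrition accounting.**  Annual death and no-show probabilities are
interpreted as per-year fractions of the *onset cohort* (period
accounting), not hazards among survivors: each patient draws at most one
exit event with per-year mass `p` for each cause over the 6-year horizon
(death wins ties).  This mirrors how clinic-level registries count
prevalent patients and reproduces the familiar "rate × years" headline
fractions (24% deceased, 12% lost); a compounding hazard would
systematically undershoot them.  Config validation requires
`(p_death + p_noshow) · horizon ≤ 1`.

**What the generator does not emulate.**  Pointwise 24-2 thresholds (only
the MD summary), IOP–treatment feedback, learning effects and long-term
fluctuation beyond iid Gaussian noise, visit-interval irregularity beyond
within-year jitter, and informative dropout (exit is independent of
disease state).  Passing recovery tests therefore show the pipeline is
correct under these idealised conditions, not that real-world estimates
are unbiased.

## Problem sizes and numerical choices

Recovery tests use 1500–2000 patients (mixture recovery within 3
percentage points is comfortably inside the binomial sampling band at
~3000 analysed eyes) and 4000–5000 patients for attrition fractions
(Monte-Carlo SD ≈ 0.6 points).  Rate-estimation equivalence against the
closed-form normal-equations oracle is asserted to 1e-10 on 1000 random
series; noise-free recovery is exact only away from the instrument floor,
so the exactness test uses a deep floor and mild severities, while the
floor-effect test does the opposite.  All randomness flows through seeded
`numpy` generators; repeated runs with the same seed produce byte-identical
serialized reports.

## Known limitations

- The eligibility predicate and the per-VF reliability rule are plausible
  operationalisations of clinic practice, not published rules.
- The alternating-eyes designation summarises shared-date comparisons by
  their mean; other summaries (per-visit majority) are defensible.
- Clinical progression labels and quality-of-life scores are carried as
  schema fields only; no computation is defined for them.
- The cost summary is a plain mean of yearly per-patient costs; no
  discounting or case-mix adjustment.
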