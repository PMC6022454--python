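# Methods

## Case definition

A person-year is a chronic-pain case if it satisfies either of two
criteria evaluated independently within one calendar year.

**Diagnosis criterion.** Every ICD-9 code on every medical claim is
classified by normalized prefix matching: codes are stripped of dots and
uppercased, and the longest configured prefix wins. Four disjoint rule
sets drive the classification — *highly likely* (default prefix `338`),
*likely* (a configurable list of non-338 chronic-pain families; the
shipped default covers spine disorders, chronic joint pain, neuropathies,
fibromyalgia and osteoarthrosis and is a documented stand-in, replaceable
via `CodeConfig` or the YAML config), *excluded* (migraine, other
headache, facial pain) and *cancer pain* (default `338.3`, carved out of
the 338 family by longest-prefix precedence). The criterion holds with at
least one highly-likely claim ("one diagnosis per calendar year" is read
as *at least* one), or with likely-code claims on two service dates whose
span (max − min, equivalent to the best pair) is ≥ `min_separation_days`
(default 30, comparator ≥). A person-year with excluded-family codes and
no include pattern is flagged `excluded_only`; an include pattern always
beats the exclusion, and the opioid criterion is unaffected by it — the
exclusion is part of the diagnosis pathway, so a person-year with only
migraine codes plus a qualifying opioid run is classified `opioid_only`.

**Opioid criterion.** Each opioid fill covers the closed interval
[fill date, fill date + days' supply − 1]; "daily use" is operationalized
as days of dispensed coverage, the standard pharmacoepidemiologic
construction, since prescriptions do not record actual consumption. Under
the default `union` overlap policy, overlapping coverage is wasted;
under `stockpile`, an early same-drug refill is shifted to begin the day
after the prior fill's coverage ends. Intervals separated by at most
`grace_gap_days` uncovered days (default 0, i.e. strictly consecutive)
are merged. Coverage is then clipped to the calendar year — a run of 50
December days plus 50 January days qualifies in neither year — and the
criterion holds when the longest run reaches `min_consecutive_days`
(default 90, comparator ≥). Clipping is a deliberate reading of "within
the calendar year"; `FinderPolicy(clip_to_year=False)` instead credits
the full length of any run intersecting the year. Fills from a prior year
are admitted as input and contribute their in-year coverage.

A person counts once per year regardless of how many patterns qualify;
the classification is `icd_only`, `opioid_only` or `both`, and the three
disjoint groups partition the cohort. Persons present only in pharmacy
claims are still evaluated for the opioid criterion.

## Prevalence and insurance attribution

Age is analysis year minus birth year (claims extracts rarely carry full
dates of birth) and is banded in five-year increments `<5, 5-9, …, 80-84,
85+`. Prevalence is 100 × cases / census population per stratum, reported
to one decimal in display tables and kept at full precision internally.
With a real claims numerator (insured persons) over a whole-population
census denominator the two universes differ, and strata dominated by the
mismatch (e.g. the elderly) can show implausibly high percentages; the
definition is reproduced as stated, and the synthetic generator avoids
the mismatch by emitting denominators from the realized population.

Payer type is a per-claim attribute. Person-year insurance is the payer
type of the majority of that person-year's claims (medical and pharmacy
pooled); ties go to public. The tie-break is a documented convention —
the source data model attributes insurance per claim and is silent on
person-level ties.

## Statistical tests

All tests are two-sided (a conservative default; published p-values do
not state sidedness). The two-sample z uses the pooled-variance form
without continuity correction — the textbook test for a difference of
proportions. The correlation test computes Pearson r on raw values and
refers `t = r√(n−2)/√(1−r²)` to t with n−2 df; "public share positively
associated with lower income" therefore appears as negative r between
income and public share. Degenerate inputs are handled explicitly:
pooled proportion 0 or 1 → statistic reported 0 with a warning; |r| = 1 →
p reported 0 with a warning; constant series and empty samples are
contract errors. No multiple-testing adjustment is applied (none was in
the source analysis); outputs carry the number of tests performed so a
reader can adjust. County-level correlations are ecological: 16 county
aggregates, no within-county variation, and no causal reading.

For county-level sex comparisons the denominator question (census
population vs cohort size) is resolved in favour of census population,
consistent with the prevalence definition; cohort-denominated tests can
be run by passing cohort counts to `two_sample_z` directly.

## Synthetic data generator

The generator emulates the observable structure of a state APCD: persons
drawn i.i.d. from county × sex × age-band marginals modelled on the 2010
Maine census profile (16 counties with approximate population shares,
median household income, poverty and bachelor's-degree rates), Poisson
background claim streams, and per-claim payer assignment. The emitted
census table contains the *realized* stratum counts, not the target
marginals, so prevalence recovery is exact rather than approximate.

Defaults are the study conditions: planted prevalence 0.33 (female) /
0.26 (male), ≈ 29.5% overall at the default sex mix, reproducing both the
reported overall prevalence and the direction of the sex difference;
case-route mix 84% `icd_only` / 13% `both` / 3% `opioid_only`, inside the
reported ranges (both 12.2–13.9%, opioid-only 2.6–5.4%, opioid-criterion
total 15.8–18.8%). Public-payer probability is income-linked per county
(0.30–0.65 across the income range) and 0.92 at ages 65+ (Medicare-age),
which plants the county-level insurance–income association; a scalar
override decouples it. Within-person claim counts are Poisson
(`benign_medical_rate` 1.2, `benign_pharmacy_rate` 0.4 per person-year) —
an explicit modelling assumption, as no claim-frequency distributions are
available to copy.

Near-miss noise is on by default because the hard parts of the rules are
the temporal boundaries: among non-case person-years, 15% get a single
likely diagnosis, 10% a likely pair 1–29 days apart, 5% excluded-family
codes only, and 5% an opioid run of 60–89 days (diagnosis-route cases can
also receive sub-90-day opioid runs, and opioid-route cases a lone likely
diagnosis). All planted patterns are wholly contained in their calendar
year, every likely-code pattern for a non-case spans < 30 days, and noise
runs stay ≤ 89 days, so labels are exact by construction under the
default policy (union, grace 0, year-clipped). With
`overlapping_fills=True`, qualifying runs are planted as early refills
(7 days of same-drug overlap) whose union span is unchanged — this
exercises the stockpile policy without altering truth under union; truth
labels are defined relative to the default policy.

Randomness comes from two streams derived from the config seed via
`SeedSequence([seed, k])` (population k=0, claims k=1), so
`generate_population` and `generate_claims` are independently
reproducible and the whole run is bit-reproducible for identical configs.

What passing synthetic tests does **not** show: real claims have coding
error and practice variation, correlated comorbidity, insurer churn,
resubmitted/duplicate claims, and the numerator/denominator mismatch
noted above. Exact planted-truth recovery validates the *algorithm*, not
the clinical accuracy of the rule on real data (the rule's positive
predictive value comes from its published validation, not from this
package).

## Problem sizes and numerical choices

The test suite and acceptance script use 1,000 fuzzed fill sets (≤ 40
fills, days' supply ≤ 120, both overlap policies, grace gaps 0–7) for
oracle equivalence, 20,000 synthetic person-years for planted-truth
recovery, 2,000 null replicates (n = 500 per arm, p = 0.295) for z-test
calibration and 500 replicates for county-correlation recovery — sizes at
which the binomial tolerances quoted in the tests are meaningful while a
full run stays in the tens of seconds. Counts in display tables are
rounded half-up; intervals are closed and all day arithmetic is integral,
so there are no floating-point tolerances anywhere in the case finder.

## Known limitations

- ICD-9 only; no ICD-10 mapping, procedure codes or claim adjudication.
- No cross-year identification (per-year cohorts by design), no severity
  grading, no morphine-equivalent dosing.
- The default likely-code and opioid lists are stand-ins; analyses of
  real data must supply the validated lists via configuration.
- Ecological correlations at 16 counties have low power and are reported
  without spatial autocorrelation handling.
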