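# Methods

## Data model and conventions

All stages share a four-table claims model (`patients`, `enrollment`,
`medical_claims`, `pharmacy_claims`) serialized as UTF-8 CSV. Dates
are day-granular and every interval is closed `[a, b]`; money is exact
integer cents; diagnosis codes are normalized (upper-case,
dot-stripped) at read time and carry their code system, since the
2012–2018 study window straddles the US ICD-9→ICD-10 transition
(2015-10-01). Diagnosis position is list order (position 1 primary);
all "MF code in any position" predicates scan the full list.
Multi-valued code fields are `|`-joined. Month-based windows are fixed
at 12 months = 365 days, 6 months = 183 days, 3 months = 91 days, and
durations in months divide by 30.4375.

## Cohort selection

The index MF date is the earliest non-diagnostic claim carrying an MF
code inside the identification window (2012-01-01 to 2018-06-30),
provided a second such claim exists with `d2 − d1 ≥ 30` days. The
"≥30 days apart" comparison is taken literally on the two qualifying
dates and tested at the 29/30-day boundary. The pre-index window is
`[index − L, index − 1]` and the post-index window `[index,
index + 182]`; the index day belongs to the post period. Diagnosis
type is primary MF if *any* qualifying claim carries a primary-MF
code. Age is computed as index year minus birth year (claims data
carry year-granular birth dates). Continuous enrollment requires every
window day covered by spans with both medical and pharmacy benefits;
abutting spans (end `d`, start `d+1`) jointly cover. Pregnancy and
clinical-trial screens are configurable code-list scans over the
pre+post windows; both qualifying MF claims must fall inside the
identification window (configurable). The RUX subgroup re-anchors on
the first RUX fill on/after the index MF date and re-applies age,
enrollment (91-day pre / 183-day post), and the exclusion screens
around that date.

## Line-of-therapy engine

A line starts at the first listed-agent event (pharmacy fill or
medical administration), transplantation, or splenectomy on/after the
index MF date. Its regimen is every listed agent with an event in
`[start, start + 29]`; an agent first seen exactly at `start + 30` is
a switch trigger, not a regimen member. Candidate end events:

* **switch** — first event for an out-of-regimen agent at
  `d ≥ start + 30`; the line ends at `d − 1`, so line 2 starts on the
  new agent's date with no overlap;
* **discontinuation** — the supply run-out (last covered day of the
  union of `[fill, fill + days_supply − 1]` over regimen agents, with
  a regimen-agent event within 45 days of a run-out bridging the gap);
  declared only if the full >45-day gap fits before follow-up end —
  a run-out within 45 days of follow-up end is censoring, because the
  gap cannot be observed (the same convention the dose-profiling stage
  uses);
* **transplantation/splenectomy**, **death**, and **censoring** at
  follow-up end (min of disenrollment and the 2018-06-30 cut-off).

The earliest candidate wins; ties break
transplant/splenectomy > death > switch > discontinuation > censoring.
A transplant or splenectomy as the *first* event opens and closes a
one-day line. Line 2 restarts the same rules at the first qualifying
event after line 1's end; lines beyond 2 are not derived. The gap
threshold is strict (`> 45` days) and configurable.

Agents administered on medical claims (azacitidine, decitabine, via
HCPCS J-codes) carry an imputed 1-day supply but a 28-day persistence
window per administration, so cycle-based drugs are not spuriously
discontinued between cycles; both values are configurable.

The engine is verified against an independent brute-force oracle
(`tests/lot_oracle.py`) that materializes coverage as a boolean day
array and finds discontinuations as uncovered runs of ≥46 days; the
two implementations agree on all 6,342 sequences of ≤4 events (two
agents, transplant, death) over a 7-point date grid.

## RUX dose profiles

Daily dose is `strength_mg × quantity / days_supply`, rounded half-up
to 1 mg; same-day fills are summed (split-strength titration packs are
one prescription). Within `[index RUX, index RUX + 182]` the profile
records the starting dose (index-day fill), the maximum dose and the
covered days dispensed at it, dose modifications (changes between
consecutive fill days after rounding; overlap-based intensification is
not modelled), a 3-month early-modification flag, discontinuation
(same observable->45-day-gap rule as the LOT engine), and therapy
duration in months. The maximum dose assigns SUB (<30 mg/day) vs OPT
(≥30 mg/day); 30 mg/day — 15 mg twice daily, the label-typical dose —
is OPT by construction and tested at the boundary.

## Comorbidity scoring

The Charlson index uses the Quan (2005) ICD-9-CM/ICD-10 mapping with
the original weights (1/2/3/6), shipped as an editable packaged CSV
whose patterns are prefixes or inclusive ranges expanded at load.
Each condition counts once; complicated diabetes supersedes
uncomplicated, metastatic tumor supersedes non-metastatic malignancy,
and moderate/severe liver disease supersedes mild. Unmapped codes
contribute nothing, so the score is monotone in the observed code set.
AHRQ categories are prefix lists for the eight reported categories;
the MF codes themselves fall inside two of them (primary MF in the
uncertain-neoplasm range D37–D48/235–238, secondary MF in the
hematologic range D65–D77/286–289), which the generator accounts for
(below). Which AHRQ tool version the original analysis used is not
recoverable; the category membership here is configuration, not a
fidelity claim.

## HCRU and costs

Office, outpatient, and ED visits are counted at claim level by
place-of-service; inpatient admissions merge overlapping or
date-abutting inpatient claims and count in a window iff the admit
date falls in it, with the stay's full cost attributed there (no
double counting across the pre/post boundary). "MF-related" is a
configured definition — any-position MF diagnosis for medical claims,
MF treatment agent for pharmacy — because no operational definition is
recoverable from the study text. Costs are combined plan + patient
paid amounts, carried in nominal-year cents and adjusted to 2018
dollars with the annual medical-care CPI at aggregation; adjustment is
applied per claim in integer cents, so the accounting identities
(medical = Σ setting buckets; total = medical + pharmacy) hold exactly
per patient. Means and SDs are taken over all cohort members,
zero-cost patients included. ED visits during an inpatient stay are
counted separately (configurable).

## Synthetic-claims generator

The generator emulates the *structure* the analysis consumes, with
defaults calibrated to the study's printed marginals: age 70 (SD 12),
54% male, 24% primary MF, 60% treated, 46% of treated with a second
line, first-line mix 39/4/31/10/16%, maximum-dose band mix from the
printed counts 68/123/276/28 (of 495), discontinuation 29% (SUB) vs
20% (OPT), mean durations 4.9 vs 5.3 months, and pre/post all-cause
cost means $24,216 / $48,966 (medical+pharmacy split and all SDs are
free parameters, flagged in the config).

Design choices that matter:

* **Calendar.** Index dates sample uniformly over 2013-01-01 to
  2017-03-31 so that even a second-line RUX window (up to ~430 days
  after the MF index) closes before the 2018-06-30 cut-off; otherwise
  window-end truncation would masquerade as discontinuation.
  Censoring is still exercised through enrollment-end/cut-off
  follow-up truncation. Enrollment spans cover `[index − ~420−600,
  index + 540]`, occasionally split into abutting spans; a small
  dropout hazard (0.005/month) ends some early.
* **Dose trajectories.** RUX fills are 30-day supplies realized as
  5-mg units so the dosing stage recomputes the intended daily dose
  exactly. Discontinuers receive `1 + Binomial(3, p)` fills with `p`
  solved in closed form from the target per-cohort mean durations, so
  the configured duration and discontinuation marginals are recovered
  by construction; non-discontinuers fill continuously to follow-up
  end. About 28% of multi-fill patients get an up- or down-titration
  within 3 months.
* **MF coding.** Because the index is *defined* as the first
  non-diagnostic MF claim, no earlier claim may carry a non-diagnostic
  MF code; pre-index MF burden is realized as diagnostic-only work-up
  labs (60% of patients). The two AHRQ categories those codes touch
  have their sampled prevalence deflated so each category's marginal
  equals the configured value. Post-index, all inpatient and 75% of
  ambulatory claims carry an MF code — the latter share calibrated to
  the printed MF-related/all-cause cost ratio.
* **Costs.** Per patient and window, medical and pharmacy totals are
  drawn from lognormals parameterized by moment matching and allocated
  across that window's claims by weight (inpatient 12, ED 2,
  outpatient 1.5, office 1; MF-agent fills 8× background fills), in
  exact cents. Drawn totals are 2018 dollars; stored claim costs are
  deflated to their nominal service year so the CPI adjustment at
  analysis time recovers them (±1 cent per claim).
* **Death** is sampled only as a LOT-end mechanism (3% of treated
  non-RUX-first-line patients, placed after the 6-month post window so
  the patient still meets the selection criteria); the rate is
  arbitrary, as no death rate is printed.
* A **ground-truth sidecar** records every sampled latent (regimen,
  band, discontinuation, covered days, comorbidity flags, window cost
  totals), enabling exact-agreement tests, not just marginal recovery.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: realistic code dictionaries or
NDC-level drug coding, provider networks, adjudication artifacts,
prevalent cases with pre-window MF history (so pre-index MF-related
costs stay small, unlike the study's prevalent-heavy cohort),
platelet-guided dose selection, correlations between comorbidity
burden and treatment or cost, and any survival structure.

## Statistics

Continuous comparisons use the two-sided Welch unequal-variance
t-test, categorical comparisons the Pearson chi-square without
continuity correction (df = k−1); the source analysis names only
"t-test" and "chi-square", so both choices are configurable and both
are verified against hand-computed closed forms. No multiple-testing
adjustment is applied, matching the descriptive design.

## Problem sizes and tolerances

Recovery tests run the full pipeline at n = 2000 patients for seeds
1–5 and accept each marginal within 3 binomial standard errors of the
generating value; cost means use 3 sample-SE bands. The oracle
equivalence check is exhaustive over its 6,342-case grid. The unit
suite uses 120–250-patient bundles; these sizes keep each pipeline run
in tens of seconds while leaving every 3-SE band well under a
percentage point of the checked proportions at n = 2000.

## Known limitations

Second-line regimen composition reuses the first-line mix (the study
prints a second-line table, but the generator does not target it);
the end-reason distribution of derived lines is emergent rather than
calibrated; "non-diagnostic" status is an explicit flag supplied by
the data rather than derived from claim type codes; and the
coordination-of-benefits process behind Medicare paid amounts is
modelled as already-resolved paid fields.
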