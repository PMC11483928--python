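# Methods

This note documents the models, conventions and design choices behind
`gpp_journey`, a pipeline for reconstructing patient treatment journeys in
generalized pustular psoriasis (GPP) from longitudinal claims data.

## Data model and date conventions

A claims bundle is three tables — patients (sex, birth year, optional
death date), dated diagnoses (ICD-10 or local codes, with a `confirmed`
flag distinguishing established from rule-out diagnoses), and dated
dispensings (drug code, optional days-supply) — plus a fixed study window
(2016-01-01 to 2021-08-31 by default).

All internal arithmetic is in integer days on calendar dates; intervals
are half-open `[start, end)` so adjacent coverage never double-counts.
Months appear only at reporting time through one fixed conversion,
30.4375 days per month (Julian year / 12, configurable). Rows with
unparseable dates are rejected with a located error, never imputed:
claims analyses must be auditable back to the input row.

## Drug catalog

Every medication class relevant to GPP carries a priority rank 1–12
(IL-17 inhibitors 1, TNF-α inhibitors 2, IL-23 inhibitors 3, etretinate
4, cyclosporin 5, apheresis/plasma exchange 6, systemic corticosteroids
7, apremilast 8, methotrexate 9, topical therapy 10, other oral
medications 11, arthritis treatment 12). Topicals, other oral
medications (antihistamines, immunosuppressants, NSAIDs) and arthritis
treatments are *supplementary*: they never change a combination line of
therapy. The priority map must be a bijection onto 1–12; the loader
rejects anything else.

Each drug also carries a discontinuation gap class — 3 months (91 days)
for biologics, 2 months (61 days) for oral drugs — and a default
coverage duration used when a dispensing has no recorded days-supply
(e.g. 28 days for monthly biologics, 84 for q12w agents such as
ustekinumab, 30 for orals, 1 day per apheresis session). Classes with no
stated gap convention (topicals, apheresis, arthritis treatments) use
the oral gap; all gaps are overridable per drug. Unknown drug codes
resolve to a supplementary "Other oral medications" fallback unless
strict mode is on.

## Cohort construction

The index date is the earliest confirmed L40.1 diagnosis inside the
study window. Patients are excluded when they have fewer than two
distinct confirmed GPP diagnosis dates (two records on one service date
count once), or when follow-up from index is ≤ 365 days — unless death
occurred within that year, which keeps the patient. Follow-up ends at
the earliest of study end, death, and last recorded claim (the data
model has no explicit disenrollment; using last activity is
configurable).

Baseline comorbidity is the Charlson index over the year before index,
computed from ICD-10 codes with the Quan coding algorithm: 17 condition
groups matched by code prefix, each scoring its original Charlson weight
once, with the usual hierarchy (metastatic disease supersedes any
malignancy, moderate/severe liver disease supersedes mild, complicated
diabetes supersedes uncomplicated). The mapping ships as a data file.

Subgroups: psoriasis vulgaris (any-time confirmed L40.0 by default;
baseline-only via configuration, since comorbid PsV describes the
disease rather than a baseline covariate) and the inclusive age bands
≥65 and ≥75 at index.

## Treatment episodes

Each dispensing covers `[date, date + supply)`. Coverage intervals of
one patient and drug merge into an episode while the off-drug gap
(next start minus running coverage end) stays within the drug's gap
threshold; a longer gap starts a new episode. Merging measures the gap
from coverage end, not dispense-to-dispense, because the discontinuation
definition describes time *off* drug. Overlapping dispensings truncate
by default (coverage never extends beyond the furthest interval end); a
stockpiling mode that carries leftover supply forward is available.
The merge is order-independent and idempotent, and equals the transitive
closure of the pairwise "within gap" relation — a property the test
suite checks against a brute-force connected-components oracle.

## Lines of therapy

A sweep-line over episode boundaries partitions each patient's window
`[index, follow-up end)` into states with constant sets of active main
and supplementary categories. States fold into numbered lines of therapy
(LOTs) under seven rules: (1) a main drug starting within the
combination window (default 30 days, the common claims convention; the
source methodology does not state a value) of the current line's start
joins it as a combination; (2) a later main-drug start opens a new line
of all then-active main drugs (add-on); (3) after all main drugs end,
the next main-drug start opens a new line regardless of similarity
(switch); (4) dropping one component of a combination opens a new line
of the remainder; (5) supplementary starts/stops never change a line
while a main drug is active; (6) supplementary-only periods form their
own line; (7) an untreated spell no longer than the largest component
gap threshold leaves the line open — the same regimen resuming continues
it — while a longer spell closes the line at last coverage end.

Simultaneous starts need no tie-breaking: they are one combination.
Labels: the *specific* regimen is the alphabetically sorted category
combination, suffixed "+ supplementary drug" when supplementary classes
co-occur; the *general* regimen is the member category with the best
priority rank. For supplementary-only lines the best-ranked
supplementary category stands in as the member. An optional
`apheresis_dominates` override lets apheresis win the general label over
higher-priority co-medication, mirroring one published grouping whose
precedence is ambiguous; the default follows strict priority.

## Survival analyses

The Kaplan–Meier estimator is implemented from first principles:
S(t) = Π_{t_i ≤ t} (1 − d_i/n_i) over distinct event times, with
Greenwood variance and units censored at an event time kept at risk at
that time. The median is the smallest event time with S(t) ≤ 0.5; its
95% CI inverts the log(-log) transformed pointwise band
(Brookmeyer–Crowley style; the transform is the most common choice in
survival software and the source methodology does not state one).
Unreachable medians and unbounded upper CI limits are reported
explicitly rather than guessed.

Time to next therapy (TTNT): each non-last line contributes
next-start − start as an event; each patient's last line contributes
time to follow-up end, censored. Drug survival: all episodes of a drug
across its recipients enter the fit; each patient's last episode of the
drug is censored, earlier episodes are events. The censoring of the last
episode is applied literally even when it ends long before follow-up
end (an alternative policy censoring only episodes ending within the
drug's gap window of follow-up end is available for sensitivity
analysis). Under this convention cohorts dominated by single-episode
recipients often have no defined KM median; the observed (event-only)
median and range are therefore reported alongside. The >1-year and
>2-year treatment proportions use cumulative per-patient on-drug days
(switchable to longest-episode).

## Pattern summaries

Sankey flows count patients by (general regimen at line k → general
regimen at line k+1) over the first three lines, with an explicit
"No further therapy" sink, so outflows are exactly conserved.
Combination frequencies count, per anchor category, the share of exposed
patients with a partner episode overlapping an anchor episode by ≥1 day.
Bio-switching takes each patient's last episode of an index biologic and
finds the first *different* biologic starting after it and before
follow-up end (restarting the same drug is not a switch); the
destination window is unbounded within follow-up by default and
configurable. All three accept cohort strata (PsV / no PsV, ≥65, ≥75),
and disjoint strata partition the unstratified counts.

## Synthetic claims generator

The generator emulates the structure the pipeline assumes: per-patient
diagnosis streams with the L40.1 index code (two confirmed diagnoses 14
days apart, quarterly follow-up visits, a final visit at end of
observation), baseline comorbidity codes, PsV prevalence 36.6%, age
~N(57.2, 19.9²), 47.5% male — the cohort mix of the population it
models — plus dated dispensings, deaths and loss to follow-up.

Pathways are a small Markov grammar over named regimen states: each
state lists its drugs, a duration distribution (exponential, Weibull or
fixed, parameterised in months), transition probabilities (residual mass
= stop) and an optional untreated-gap probability. Dispensings are
emitted at each drug's cadence with the final fill's supply trimmed so
coverage ends exactly on the line boundary — the crisp boundaries that
make ground truth exact. The generator validates that adjacent states
differ in main-category composition (a same-category switch would be
invisible to a category-level algorithm) and keeps preset line durations
≥ 100 days so a drug recurring two lines later can never bridge its
91-day gap at episode level. Ground truth (index date, follow-up end,
line sequence with TTNT and censor flags, episode boundaries) is defined
under the package's documented rules and written through the same CSV
schema as real data, so tests exercise the true I/O path.

Presets: `simple_switching` (monotherapy pathways, first-line mix
dominated by etretinate, topicals, cyclosporin and corticosteroids with
biologics increasing in later lines), `combinations` (multi-drug
regimens, add-ons, component discontinuations, 50% supplementary
attachment), `bio_switch` (cross-class biologic switching, 30% of
transitions after a 100–180-day untreated spell), and `edge_cases`
(documented boundary patients: a single confirmed diagnosis, a
short-follow-up survivor, death within the first year, same-day
combination starts, a single dispensing).

Noise injection is bounded and labelled: fill-date jitter must stay
strictly below the smallest gap threshold (episode counts provably
unchanged), and injected holes must exceed the target drug's threshold
(the episode provably splits; episode ground truth is re-derived, and
line ground truth is flagged invalid since main-drug holes change it).

What the generator does *not* emulate: real claims coding noise
(miscoding, duplicate claims systems), hospital-level effects,
drug-launch calendar effects, dose/route detail, or ambiguous overlaps
at rule boundaries outside `edge_cases`. Passing recovery tests
therefore shows the algorithms implement their stated rules exactly, not
that the rules capture every messy real-world record.

## Problem sizes and numerical choices

Recovery tests run three presets at 300 patients over five seeds each;
statistical recovery uses 2000 patients/samples, where the Monte-Carlo
error of a median is ~2–3%, comfortably inside the 5% check. The KM
implementation is cross-checked against an independent reference
(lifelines) to 1e-10 on random samples; exact S(t) = 0.5 ties are
resolved as "median = the tied time". Survival durations are floored at
one day. Report CSVs are written with fixed float formatting so
identical inputs are byte-identical.

## Known limitations

- The line-of-therapy algorithm works at category granularity; a switch
  between two drugs of one category with seamless coverage is invisible
  (by design, matching category-level regimen labelling).
- The combination window (30 days) and the "other" gap class (61 days)
  are conventions, not published values; both are configurable.
- CI inversion for the median can return degenerate bounds with very few
  events; they are reported as-is.
- The generator's pathway grammar has no within-line dose changes and no
  concurrent independent supplementary courses outside line spans.
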