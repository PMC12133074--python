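# Methods

## Problem and scope

`gpprenatal` implements an interrupted time-series (ITS) analysis of pregnant
women's general-practitioner (GP) contact rates across the COVID-19 pandemic,
together with the upstream electronic-health-record (EHR) cohort-identification
procedure and two companion analyses (ICPC code-frequency surveillance and
contact-type mix). The source EHR data the design emulates — three regional
Dutch GP research networks, roughly 410,000 patients — are not publicly
available, so the package ships a first-class synthetic EHR generator with a
ground-truth ledger; every analysis stage is exercised and validated end to end
on data whose generating parameters are known.

## Phase calendar

The study window (2019-01-01 to 2021-12-31) is partitioned into a prepandemic
baseline (phase 0: all of 2019 plus 2020 ISO weeks 1–8) and twelve pandemic
subphases (1a…6b) delimited by ISO-8601 week numbers; the main phases follow
national restrictive measures and the subphases follow turning points in
national infection rates. Dates are assigned through their own ISO year/week,
so 2019-12-30 (ISO 2020-W01) is baseline and 2021-01-01 (ISO 2020-W53) falls
in subphase 3b. Only weekdays are calendar members; within each subphase the
clock `t` counts calendar days since the subphase's first weekday. Seasons are
meteorological (winter Dec–Feb, spring Mar–May, summer Jun–Aug, autumn
Sep–Nov); the season boundaries are a package decision since only the season
names are prescribed by the design.

## Cohort identification

Pregnancy status is established per contact by three routes:

1. **ICPC codes** — at least one code from a configurable pregnancy/
   childbearing set (default: 24 chapter-W codes). Sub-coded registrations
   match through their base code (W84.02 matches W84). Miscarriage codes are
   pregnancy-defining. W90 ("normal delivery liveborn") is hard-excluded from
   the defining set because of false carry-over registrations; validation
   refuses a set containing it. The default set is package data, not a claim
   of fidelity to the original (unpublished) study list.
2. **Free text** — a case-insensitive regular expression over the physician's
   note (default: a small Dutch lexicon, `zwanger|gravid…|weken amenorroe`).
   A text match alone only makes the contact a *candidate*.
3. **Manual assessment** — a machine-readable verdict table
   (`contact_id, confirm/reject`) standing in for the human review step. A
   text candidate is confirmed only by a manual `confirm`; a manual `reject`
   overrides even an ICPC match.

Contacts where no route is irrefutable are excluded as indeterminate. The
exclusion cascade then removes patients — death in the study period,
deregistration within the period, a deregistration reason without a date,
unknown birth date, registration shorter than `min_registration_days`
(default 90 days; "less than 3 months" is not defined in days anywhere, so
the count is configurable), missing pseudonymization data — and contacts:
age outside 20–45 *at the contact date* (a package decision; "at study start"
was the alternative), weekends, national holidays (default Dutch holidays
2019–2021, configurable), and out-of-office-hours contacts. Every entity is
audited once, at the first rule that removes it, so the audit reproduces a
flowchart: input = included + Σ removals.

## Contact-rate model

Daily rates are normalized per 1000 registered pregnant patients:
`rate(d) = 1000 · contacts(d) / denominator(d)` over weekdays minus holidays.
The denominator ("registered pregnant patients on day d") is not fully
determined by the design; the default (`year_label`) counts women with an
active practice registration on `d` who have a confirmed contact in the
calendar year containing `d`. Alternatives: `registered` (any confirmed
contact in the study) and, on synthetic data, `truth_episode` (the
generator's own denominator, for recovery checks), or an explicit
`denominators.csv`.

A centered moving average of 15 weekdays (3 weeks × 5 weekdays) stabilizes
the series before modelling; edges use a shorter symmetric window. By default
the average runs across subphase boundaries (`within_subphase` restarts it at
each boundary).

Per subphase `P` the seasonal segmented regression is fit by OLS:

    Y_t = β0 + β1·t + β2·S1 + β3·S3 + β4·S4 + ε

with `t` days since the subphase start (so β0 is the level at the start of
the subphase), spring as the seasonal reference and dummies for winter (S1),
summer (S3) and autumn (S4). Season dummies absent from the subphase are
dropped and flagged. When spring itself does not occur in a subphase the
dummies would be collinear with the intercept, so the model re-references to
the subphase's first season (that season's offset is absorbed into β0 and
the fit records `reference_season`). Coefficient SEs come from the standard
OLS covariance; a Newey–West (HAC) option exists but is off by default —
residual autocorrelation is surfaced through an ACF diagnostic rather than
corrected for, mirroring the emulated analysis. R² and adjusted R² are
reported; a zero-variance response yields NaN (SS_tot = 0, so neither 0 nor
1 would be honest).

Each pandemic subphase's intercept and slope are compared with the baseline
by a two-independent-estimates Wald z,

    z = (β_P − β_0) / sqrt(SE_P² + SE_0²),

with a two-sided P from the standard normal and α = 0.05. The reference
study's published z/P columns are internally inconsistent (their convention
cannot be inferred), so this package documents its own convention and does
not attempt to reproduce those columns. The baseline is never compared with
itself.

## Code-frequency surveillance

From a configurable list of pregnancy-relevant codes (tagged
pregnancy-related vs general), the top 10 by registration count are ranked
(ties broken lexicographically; a contact with m relevant codes contributes
m registrations). For each top code and pandemic subphase a two-sided Fisher
exact test (probability-mass summation, via `scipy.stats.fisher_exact`)
compares the code's frequency with baseline, with rates per 1000 contacts
attached. Whether the proper unit is contacts or registrations is ambiguous
in the emulated design; both are computed (`code_test_unit`), contacts being
the default. Degenerate margins report P = 1 with a flag. No multiple-testing
correction is applied by default — the report warns about the number of
nominal-level tests — and Benjamini–Hochberg is available as an option.

## Contact-type mix and descriptives

Per-date proportions of the four contact types (clinic, home visit,
telephone, digital) are smoothed per type by the same centered moving average
and renormalized to sum to one. For display, a locally weighted polynomial
smoother (LOESS) with tricube weights over the `ceil(span·n)` nearest
neighbours is available. Boundary convention: when the local window covers
the entire series the weights are uniform, so span = 1 with degree 1 reduces
exactly to the global least-squares line; for any span, exactly linear input
is reproduced exactly (a local line fits a global line everywhere).

Year-level summaries report pregnant women with ≥ 1 included contact per
year (populations may overlap across years), total contacts, mean (sample
SD, n−1) contacts per patient, mean (SD) ICPC registrations per contact and
mean (SD) age at the first contact of the year. Across-year count
comparisons use the likelihood-ratio G-test, `G = 2·Σ O·ln(O/E)` over cells
with O > 0, df = cells − 1, chi-square upper tail, with equal expected
counts as the (documented, assumed) null. The G statistic is computed by the
masked direct formula because zero observed cells must contribute zero.

## Synthetic-data generator

The generator's defaults are the study conditions:

- **Population** — `n_patients` women (default 5000 for the end-to-end runs),
  ages drawn so everyone is 20–45 at some point in range; pregnancy
  prevalence 0.139; one pregnancy episode of 280 days per pregnant woman,
  uniformly placed; per-rule exclusion-trait fractions of 0.5–1%.
- **Contacts** — population-level daily counts per weekday, Poisson with mean
  `intensity(d) · denominator(d)/1000`, attributed uniformly to women whose
  episode covers the day. The intensity is piecewise linear per subphase with
  seasonal offsets; default intercepts/slopes take the magnitudes of the
  published segment fits (intercepts ≈ 8–11 per 1000 per day, |slope| ≤ 0.08)
  and seasonal offsets of −0.4 (winter), +0.5 (summer), −0.2 (autumn). The
  Poisson choice is an assumption — the emulated design states nothing about
  the noise beyond linear-model residuals.
- **Detection channels** — every truth-pregnant contact carries at least one
  pregnancy-defining ICPC code, except a `text_signal_rate` (default 5%)
  fraction that instead carries only a Dutch pregnancy phrase in its note.
  A non-pregnant background stream (constant 3 per 1000 per day) supplies
  negatives, with decoy phrases ("niet zwanger", "zwangerschapstest
  negatief") in 5% of its notes. A complete manual-label table can be derived
  from the truth ledger (`confirm` for text-only contacts, `reject` for
  decoys).
- **Contact types** — per-subphase multinomial mix; baseline 64.9% clinic /
  31.7% telephone shifting toward telephone during the pandemic.
- **Codes** — one primary code per contact from a per-subphase emission
  distribution (with bumps emulating, e.g., the gestational-diabetes signal),
  plus Poisson(0.13) extra general codes.
- Weekends and holidays generate no contacts (the analysis excludes them
  anyway). A single seed feeds named per-stage substreams
  (population/episodes/contacts/background) via `numpy` `SeedSequence.spawn`,
  so identical config + seed gives byte-identical output files.

What the generator does **not** emulate: gestational-age progression, parity,
practice-level clustering, per-patient contact propensity (contacts are
population-level and attributed uniformly), infection dynamics, and any
dependence between note text and code beyond the detection channels. Passing
tests therefore demonstrate the correctness of the pipeline's arithmetic,
labelling logic and estimators under the stated model — not robustness to
real-EHR messiness such as coding drift or informative missingness.

## Validation strategy and problem sizes

- **Noise-free recovery**: rates generated without noise are piecewise linear
  by construction; every coefficient is recovered to < 1e-6 (measured at
  ~1e-14).
- **Coverage**: 100 seeded replicates with Poisson noise at denominator
  100,000; each coefficient class (intercept, slope, seasonal) covers its
  generating value within ±2 estimated SE in ≥ 90% of fits (measured ≈ 94%).
  The recovery studies fit the *unsmoothed* rates: the 15-weekday moving
  average deliberately leaks across subphase boundaries and autocorrelates
  the noise, which is appropriate for the descriptive fits but would bias a
  calibration check; this is the package's own validation design.
- **Oracle equivalence**: the OLS path is checked against a closed-form
  normal-equations solver (1e-8), the Fisher P against full hypergeometric
  enumeration (margins ≤ 40), the G statistic against a direct-formula loop
  (1e-10), the moving average against a brute-force loop, and the LOESS
  against the exactly-linear reproduction property.
- **Truth recovery**: with a complete manual-label file, the included contact
  set equals an independently reconstructed ground-truth inclusion set
  exactly, and the exclusion audit conserves counts.
- **End-to-end**: the default 5000-patient, 3-year run completes in seconds
  and produces a schema-valid bundle; reruns are byte-identical.

Pipeline-scale runs use 2500–5000 patients; these sizes give per-day
denominators of a few hundred, which is enough for all distributional checks
(binomial/Poisson/multinomial 99% bounds) while keeping the full suite in
seconds.

## Known limitations

- The default pregnancy-code list and text pattern are reasonable stand-ins,
  not the original study's (unpublished) Supplementary lists; users with
  access to validated lists should supply them through the configuration.
- The label-based rate denominator undercounts relative to the generating
  truth (women without a confirmed contact in a year are invisible), so
  pipeline-level rates on synthetic data sit above the generating intensity
  unless the truth denominator is selected. This reflects a real property of
  observational cohort labelling, not a bug.
- OLS SEs ignore residual autocorrelation of the (optionally smoothed) daily
  series; the HAC option is provided but changes no default output.
- The published segment-fit table cannot be reproduced without the source
  EHR; it is used only as the source of realistic generating magnitudes.
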