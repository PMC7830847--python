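# Methods

This note documents the models and procedures `lungqi` implements, the
assumptions behind them, the parameters that matter, what the synthetic
data generator does and does not emulate, and the design choices made
where the underlying methodology left room.

## Cohort definition

The base population is every registry case with ICD-O-3 topography
C33–C34 diagnosed in the study years. Two exclusions are applied, in
order: death-certificate-only (DCO) cases and mesenchymal histologies
(morphology 8800–8999). Histology grouping is deliberately coarse:
SCLC iff the case is cyto-histologically confirmed with morphology
8041–8045; everything else — including nonspecific codes and unconfirmed
cases — is treated under NSCLC rules, since those guidelines apply by
default.

**Charlson comorbidity index.** The published modification we follow is
the common registry-linkage form: the standard 17-condition weights, a
12-month lookback ending the day before incidence, inpatient and
outpatient codes only, distinct conditions counted once, and all
malignancy categories removed from the dictionary (the index cancer
would otherwise score every patient). Classes are 0 / 1–2 / ≥ 3 for
stratification and 0 / 1 / 2 / ≥ 3 for description.

**First therapy.** The earliest surgery, chemotherapy or radiotherapy
event on or after incidence, within a 180-day ascertainment window
(matching the 180-day contact window of the access indicator). When the
earliest modality is medical and the first chemotherapy and first
radiotherapy starts lie within 90 days of each other, the first therapy
is chemo-radiation, dated at the earlier start. "Month" is 30 days,
"3 months" 90 days, and every interval includes both endpoints.

**Provider attribution.** For each indicator a patient is attributed to
the provider of the earliest relevant procedure (the first lung surgery
for surgical indicators, the first qualifying biopsy for the
biopsy-pathway indicator, the earliest recorded contact for
population-wide indicators). Same-day ties break to the
lexicographically smallest provider ID for reproducibility. Indicators
whose numerator is itself the treatment (e.g. receipt of
chemo-radiation) attribute by first contact, not by treatment —
otherwise denominator members who never received treatment would be
unattributable and the provider profile would condition on the outcome.

## Indicator engine

All 22 definitions are data, not code: a definition is a composition of
primitive predicates (`has_event` over a code set in an inclusive day
window relative to an anchor, `stage_in`, `histology`,
`received_chemoradiation`, `not_deceased_within`, `stay_le`, ...) with
anchors at incidence, first therapy, first surgery, its discharge, first
biopsy, or death. The numerator is evaluated only for denominator
members. Negative-direction indicators (no death within 30 days of
surgery; no second resection within 30 days) are computed exactly as
stated, with absence as the success.

Three readings had to be fixed where the published wording and the
published counts could not both hold:

* The PET-before-curative-treatment indicator uses *all* NSCLC stage
  I–III patients as its denominator (untreated patients count as
  failures); the numerator is a PET in the 90 days preceding first
  therapy. The printed denominator is impossible under the
  received-treatment reading.
* "Receiving chemo-radiation" means two different things: for the
  stage II–III treatment indicator (and first-therapy classification) it
  is chemo and radiotherapy each starting within 90 days of the other;
  for the metastasis-workup denominator it is receipt of both modalities
  in any sequence. The printed counts force the distinction.
* The "contact" that anchors the first-contact-to-therapy indicator is
  any recorded event in any of the four event tables in the 180 days
  before first therapy.

**Feasibility audit.** An indicator is infeasible when any code token it
requires is absent from the databases or used by fewer than 5 % of
providers (boundary inclusive). This reproduces the situations in which
a procedure exists in clinical practice but not in billing data:
multidisciplinary evaluations billed by 2 of 92 providers, pre-surgical
lung-function tests never billed separately, palliative-care records not
covering the whole territory.

**Clinimetrics.** Provider distributions are summarised with the mean,
SD, median and quartiles (linear interpolation between order statistics)
and the counts of providers at exactly 0 % (floor) and exactly 100 %
(ceiling).

## Consensus round

Retention requires, over the respondents who completed all three
questions for the indicator, validity ≥ 5 in at least 75 % and
modifiability and utility ≥ 4 in at least 50 % (all inclusive). The
three fractions share one denominator — complete responders — because
item-level missingness is treated as partial completion. The in-person
second round changed wording only, so it has no computational footprint
beyond the one panel-proposed indicator entering the set.

## Criterion validity

The validation subsample is proportional stratified (histology × stage
group × first treatment, remainders by largest fraction), deterministic
per seed. A record is discordant only in one direction: procedure in the
chart, code absent from the databases in the correct window
(chart = 1, database = 0). The reverse direction is tracked but never
counted toward the threshold. An indicator is eliminated when strictly
more than 20 % of evaluated records are discordant; the follow-up
indicator is exempt (complete records for the follow-up period are not
available for abstraction) and passes through retained.

## Reliability

Noise is the sampling variance of a proportion at the provider's
caseload, p̂(1−p̂)/n_j, with p̂ the overall indicator proportion — using
the pooled p̂ avoids degenerate zero noise at providers sitting at 0 % or
100 %. Signal is the between-provider variance τ² of a random-intercept
logistic model (fixed effects: age stratum, sex, stage group, Charlson
class; grouping: provider), estimated by maximising the Gauss–Hermite
marginal likelihood (25 nodes, L-BFGS-B over fixed effects and log σ, so
τ² ≥ 0 by construction; non-convergence raises with the iteration
trace). Because τ² lives on the log-odds scale and the noise on the
probability scale, the default converts the signal with the delta
method, τ_p² = τ²[p̂(1−p̂)]²; the naive unconverted ratio is available as
`scale="logit"` for comparison. Reliability is 100·signal/(signal+noise),
undefined when p̂ ∈ {0, 1}, reported per provider and summarised as the
count and share at or above 70 %. Providers with a single evaluated
patient are kept but flagged low-information.

## Synthetic data generator

The generator emulates the *structure* of a six-year population cohort
of ~5,750 eligible lung-cancer patients: the raw registry (5,860 rows
including 88 DCO and 26 mesenchymal cases), sex (75 % male), the
seven-class age distribution, incidence years, stage (including a
15 % missing-stage class), cyto-histological confirmation (83.8 %),
histology split, comorbidity classes, the five-way first-treatment mix,
the survival chain (deceased at censoring, alive after 2/3/4 years), and
— centrally — the published numerator/denominator pair of every
computable indicator, reproduced *exactly* by construction.

It works in two layers. A **joint profile allocator** solves the
published counts into a full cross-classification (histology × detailed
stage × treatment × surgery subtype × imaging-lag category × survival
class), checking feasibility at every step and raising a named
`CalibrationError` on impossible target combinations; detailed stages
(IIA/IIB, IIIA/IIIB) exist precisely because the early-stage surgical
targets and the stage I–III denominators cannot be reconciled without
them. An **event planner** then places each patient's events at offsets
that realise exactly the memberships their profile prescribes — the key
device is a three-rung "contact ladder" (therapy at 30/60/180 days after
incidence) that controls membership in the first-contact indicator
without disturbing any other window. Numerator membership within each
quota is drawn with provider-effect-weighted selection (logistic
tie-break noise), so the calibrated cohort carries genuine
between-provider signal of the configured variance τ² (default 0.3 on
the log-odds scale, a moderate degree of profiling heterogeneity; the
published analysis reports no value).

Known deviations, fixed once and documented:

* The published comorbidity table undercounts the cohort by 303
  patients; the class-0 share (56.7 %) and the "43 % with index > 0"
  statement are preserved and the remainder spread over the non-zero
  classes.
* The published survival chain makes the follow-up year-4 denominator
  internally impossible (deceased-at-censoring forces 948 patients alive
  after four years, not 892, because every fourth anniversary falls
  before the censoring date). The generator realises 948 and keeps the
  published numerator; the year-4 value is therefore 75.4 % rather than
  80.2 %, and the generation sidecar records the deviation.
* One printed numerator (survival after first surgery) is reconstructed
  as 1,115 from the printed denominator and percentage, the digits being
  ambiguous in the source table.

What the generator does **not** emulate: realistic disease progression
or survival curves (death days are uniform within their chain windows),
correlation between demographics and treatment (sex, age, year and
comorbidity are quota-assigned independently of the clinical profile),
code multiplicity (one event usually stands for a course of treatment),
and chart-review errors beyond the one-directional miss model. Passing
tests therefore demonstrate that the *rules* are implemented exactly and
that the pipeline's decisions reproduce under the published conditions —
not that the generator is a realistic patient-level simulator.

The panel simulator is quota-based: per candidate, the configured
fractions of responders clearing each scoring bar are hit exactly, which
makes the round-1 outcome (13 of 34 excluded) deterministic while
individual scores stay stochastic. The chart-review simulator models the
chart as the truth the databases under-capture; in rate mode the
discordant count is the floor of rate × n, so a below-threshold
published rate stays below threshold at any subsample size.

## Problem sizes and numerics

Default runs use the full ~5,750-patient cohort; generation takes a few
seconds and the complete pipeline (including ~18 hierarchical-model
fits) well under a minute on one core. Parameter-recovery checks for τ²
use 100 providers × 50 patients over 20 replicates, which bounds the
median relative error near the information limit of that design.
Quadrature uses 25 Hermite nodes; reducing to 15 changes τ̂² in the third
decimal on these sizes. Proportions with empty denominators are flagged
undefined rather than reported as zero.

## Limitations

Real deployments must remap the abstract code tokens in
`data/codes.yaml` to the local coding systems, and the exact published
Charlson modification and first-therapy supplement were not available —
the implemented variants are the standard registry-linkage choices and
are configurable. The stage substructure of the synthetic cohort (IIA
vs IIB, IIIA vs IIIB splits) is constrained by the indicator targets but
not uniquely determined by them; the allocator's residual choices are
deterministic and seeded.
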