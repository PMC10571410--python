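# Methods

This note documents the models, conventions and numerical choices behind
`mhqi`: what each pipeline stage assumes, which knobs matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Data model

A region is an `EventStore`: seven event tables (patient registry,
outpatient contacts, hospital admissions, drug dispensations, residential
stays, laboratory/specialist services, diagnosis assignments) linked by a
pseudonymous patient identifier, plus a declared data horizon, an ICD
dialect (ICD-10 or ICD-9-CM, handled uniformly by code-prefix matching) and
a list of services the region's systems do not record.  Dates are whole
calendar days (ISO-8601); stays are inclusive at both ends and
length-of-stay is discharge − admission in days.  On load, rows referencing
patients absent from the registry are dropped and counted in an audit
report rather than aborting the run — mirroring real-world linkage loss —
while schema violations and unparseable dates fail loudly with file and
line information.

Code lists are configuration, not code.  The shipped defaults —
personality disorders = ICD-10 F60–F61 and ICD-9-CM 301.\*; antipsychotics
= ATC N05A excluding lithium salts (N05AN); lithium = N05AN01;
valproate/carbamazepine = N03AG01 and N03AF01; lamotrigine = N03AX09; mood
stabilizers = all antiepileptics (N03A) plus lithium; antidepressants =
N06A; "psychotropic" (for the washout) = the union — are standard classes
and deliberately provisional: any study-specific list can replace them via
`coding_maps.yaml`.  The mood-stabilizer class is wider than its two
printed sub-rows because class-level exposure in practice includes other
antiepileptic stabilizers.  ATC resolution is longest-prefix, so
molecule-level entries and exclusion carve-outs override class-level ones.

## Cohorts

The prevalent cohort of a recruitment year: age 18–65 at index (completed
years), a qualifying personality-disorder code dated in the recruitment
year, and at least one contact with a department of mental health that
year.  "Contact with a DMH" includes outpatient contacts in any setting
(community centre, day centre, *or home*), GHPW admissions, and
residential-facility entries; home contacts are included because the
indicator counting CMHC/DC contacts sits well below 100% in real data
while hospital and residential admissions alone cannot account for the
gap — the information system records home interventions as contacts too.
The index date is the first such event; same-day ties break contact >
admission > residential (arbitrary but fixed).

Newly-taken-in-care washout, applied to prevalent members in order: (i) any
personality-disorder diagnosis strictly before index, (ii) any GHPW
admission before index, (iii) at least two *consecutive* psychotropic
dispensations in the 730 days before index, where consecutive reuses the
episode gap rule (end of supply to next start < 90 days); then the age band
narrows to 18–40.  Each removal carries one trace per failed criterion.  A
lookback that extends before the data horizon is logged; the patient is
retained unless a disqualifying event is actually observed (deterministic,
and conservative in the same direction as the residual-uncertainty age
restriction).

Follow-up is 365 days from index.  Person-years are exactly 1.0 for a
complete window and (death − index)/365.25 for deaths inside it.  The two
conventions are deliberate: the whole-window contribution must be exactly
one (intensity denominators), while partial windows use the standard
365.25-day year.

## Episodes and persistence

One DDD supplies one day; a dispensation of *q* DDD covers ⌈q⌉ days from
its date.  With stockpiling (default on, configurable) supply that overlaps
existing stock is shifted forward to start when the stock runs out.
Episodes chain prescriptions whose end-of-supply → next-start interval is
strictly below `gap_days` (default 90); an interval of exactly 90 days
already interrupts.  Episode class granularity is the drug class, so
switching molecules within a class does not interrupt.

Drug persistence over a follow-up window: the patient enters at their first
in-window dispensation; they are persistent when the supply chain
containing it — merging across sub-threshold gaps and counting hospital and
residential days as covered time — leaves no refill-free interval of ≥ 90
days while the patient is under observation.  Concretely, supply (or a
bridge) must reach into the final 89 days of the window.  The alternative
convention (treating the window end itself as a missed refill) fails a
sanity limit: with a 1-day threshold, a patient covered every single day
must remain persistent.  Community persistence is the same day-grid idea
with CMHC/DC contact days as coverage: every maximal uncovered stretch of
the window, including before the first and after the last contact, must be
shorter than 90 days.  Hospital/residential bridging applies to both
notions; it is the uniform reading of "time spent in hospital and
residential wards is continuity of care" and sits behind the same
`gap_days` configuration.

Both engines are validated against brute-force day-grid oracles (stock
simulated one day at a time) on randomized histories, including the exact
90-day boundary.

## Indicators

All 33 indicators are reductions of one per-patient feature table, so their
conventions live in one place:

- "treated with class X" = ≥ 1 dispensation of X during follow-up (the
  printed tables carry no minimum-exposure qualifier);
- intensity medians (contacts, visits, sessions, days per person-year) are
  computed among users — patients with ≥ 1 qualifying event — because each
  printed median row is paired with a "patients with at least one…" row;
  even-sized pools take the mean of the central pair;
- readmission indicators use the admission as the statistical unit:
  denominator = all in-window GHPW admissions of cohort members, numerator
  = unplanned admissions starting within 7/30 days (inclusive) of the
  patient's previous discharge; the first-ever admission cannot count;
  overlapping admission records are merged with a warning;
- discharge-follow-up indicators count only discharges whose 14-day
  observation window fits inside follow-up (complete observability, avoids
  right-censoring bias), and a qualifying contact must fall strictly after
  the discharge day;
- monitoring indicators require the complete configured panel within
  follow-up (antipsychotics: glycaemia + lipid panel; lithium: lithaemia +
  electrolytes; valproate/carbamazepine: blood count + transaminases;
  lamotrigine: blood count) — defaults editable, and a panel may be
  completed by services ordered for another co-dispensed class;
- continuous-community-care uses the full cohort as denominator (the
  with-≥1-contact alternative is a one-line change of the reduction);
- the SMR applies reference age-band/sex mortality rates to accrued
  person-years for E, with O the in-window deaths.

An indicator a region cannot inform (e.g. psychoeducation or home-care
recording) is flagged unavailable, rendered blank with a footnote, and its
region is excluded from the pooled numerator *and* denominator.

## Pooling and heterogeneity

Pooling is aggregate fixed-effect: summed numerators over summed
denominators, making the whole-sample proportion the denominator-weighted
mean of regional values — the convention that reproduces published
whole-sample columns from regional ones, and the reason no random-effects
model is offered.  Homogeneity: Pearson χ² of the regions × {event,
non-event} table, df = regions − 1, for proportions; one-way ANOVA of the
per-patient rates across regions for intensity rows, converted via
Q = F × df_between.  I² = max(0, (Q − df)/Q) × 100, clipped to [0, 100],
banded with closed upper boundaries (25 → Negligible).  The whole-sample
intensity value is the denominator-weighted mean of regional medians: a
documented surrogate, since aggregate data cannot recover the patient-level
median; a test quantifies (without asserting away) its divergence.

SMR confidence limits are exact Poisson, χ²-quantile form: lower =
qχ²(0.025, 2O)/2E (0 when O = 0), upper = qχ²(0.975, 2(O+1))/2E — chosen
over Byar/normal approximations because they are oracle-checkable by tail
summation and correct at O = 0.  Simulated coverage over 2,000 draws is
≈95.3%.  Treated prevalence is directly standardized: Σ w_s (count_s /
pop_s) × 10⁴ with configurable reference weights (default: the pooled
synthetic population), reducing to the crude rate when the reference equals
the study population.

## Synthetic regions and the ground-truth ledger

The generator's purpose is testability: every scenario parameter is either
an exact per-patient marginal of the matching indicator (cohort-entry
contact, drug-class exposure, ward admission, residential admission are
independent Bernoullis — so the pipeline estimate of each is an unbiased
estimate of the parameter) or a shape parameter (Poisson contact
intensities placed uniformly in the window; lognormal ward and residential
stay lengths; chained 7/30-day readmission probabilities; per-class
monitoring panels with partial-completion noise).  Community and drug
persistence are planned per patient (anchor contacts every ≤ 85 days, or a
planted ≥ 90-day contact-free tail; monthly refills, or an early stop), but
the *ledger records the realized truth*, recomputed from the events
actually emitted with day-grid routines independent of the episode engine —
because deaths truncate streams and hospital stays can bridge planted gaps.
Non-newly patients aged ≤ 40 always carry at least one planted washout
disqualifier (prior diagnosis, prior ward admission, or a consecutive
dispensation pair in lookback); older patients carry one with configurable
probability.  Deaths follow baseline age/sex mortality times a true SMR
multiplier.  Generation is deterministic given (scenario, seed), with
streams keyed by seed *and* region label.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlation between service use and drug
exposure beyond the planned persistence patterns, seasonality, regional
case-mix and age gradients in prevalence (prevalence is uniform across
strata so crude and standardized rates coincide by design), coding errors,
re-entry after mid-year disengagement, or cohort-specific behaviour of the
newly-taken-in-care (both cohorts share one parameter set per region).
Intensity medians run somewhat above `contact_rate` when typed
interventions are dense, since typed sessions add to the generic stream.

## Problem sizes and determinism

Default test fixtures use regions of 200–600 patients; ledger-equality
acceptance runs use three regions of 5,000; parameter recovery uses 50
replicates of 5,000-patient cohorts with a sparse event scenario (only the
four structurally mapped indicators' streams active).  The acceptance
script generates the four default regions at their full published-style
sizes (31,688 prevalent patients) and completes in well under a minute.
All randomness flows from explicit integer seeds; reports embed a
configuration hash and regenerate byte-identically.

## Known limitations

- The exact published code lists and intervention catalogue are not public;
  defaults are standard but provisional, and results shift with them.
- Median pooling is a surrogate (see above); pooled intensity rows are not
  comparable to patient-level pooled medians.
- The washout's left edge depends on the data horizon; patients with
  censored lookback are retained with a logged warning.
- "Unplanned" is taken from the admission record as-is; no inference is
  attempted when the flag is missing.
- The SMR uses a two-band age reference; finer stratification only requires
  a larger reference table.
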