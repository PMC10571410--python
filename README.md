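# mhqi — quality-of-mental-healthcare indicators from administrative data

`mhqi` turns harmonized healthcare-utilization (HCU) event tables — patient
registries, community mental-health contacts, hospital admissions, drug
dispensations, residential stays, laboratory services and diagnoses — into a
grid of **33 clinical quality indicators** for patients with personality
disorders, per region and pooled across regions.  It is aimed at
pharmacoepidemiologists and mental-health services researchers who evaluate
care pathways on administrative claims, and at anyone who needs a fully
testable stand-in for confidential regional databases: a synthetic
multi-region generator with a per-patient ground-truth ledger ships as a
first-class, tested module.

## What it computes

**Cohorts.** The *prevalent* cohort of a recruitment year contains patients
aged 18–65 with a personality-disorder diagnosis (ICD-10 F60–F61 or ICD-9-CM
301.\*, configurable) and ≥ 1 contact with a department of mental health that
year; the first contact is the index date and follow-up runs 365 days.  The
*newly-taken-in-care* sub-cohort applies an incident-user washout — no prior
diagnosis, no prior psychiatric-ward (GHPW) admission, no two consecutive
psychotropic dispensations in a 2-year lookback — then restricts to ages
18–40.  Every exclusion is traced with its reason.

**Treatment episodes and persistence.** A dispensation of *q* defined daily
doses (DDD) supplies ⌈q⌉ days; overlapping supply is carried forward
(stockpiling).  Prescriptions are *consecutive* when the interval from end of
supply to the next start is < 90 days; an interval ≥ 90 days closes the
episode and, inside follow-up, marks discontinuation:

    persistent  ⇔  no refill-free interval ≥ 90 days occurs under observation,

with days spent in hospital or residential care counted as covered time.
Community-care persistence is analogous with outpatient CMHC/DC contacts:
every maximal contact-free stretch of follow-up must be < 90 days.

**Indicators.** The catalogue covers accessibility/appropriateness (1–23:
contact, psychiatric-visit, assessment, psychosocial, psychoeducation,
psychotherapy and family-intervention coverage and intensity per
person-year; drug-class exposure; residential and ward admission, long
stays, 7/30-day unplanned readmissions), continuity (24–28: continuous
community care, mood-stabilizer persistence, 14-day post-discharge
follow-up) and safety (29–33: monitoring panels per drug class and the
standardized mortality ratio).  Intensity rows are medians among users of
events per person-year; readmission rows use the admission as statistical
unit.

**Pooling.** Regional estimates are pooled by aggregate (fixed-effect)
summation, so the whole-sample proportion is the denominator-weighted mean
of regional values.  Homogeneity is tested with the Pearson χ² of the
regions × {event, non-event} table (one-way ANOVA for intensity rows) and
expressed as

    I² = max(0, (Q − df) / Q) × 100,

banded Negligible (0–25], Moderate (25–50], Substantive (50–75],
Considerable (75–100].  The SMR is O/E with exact Poisson 95% limits
(χ²-quantile form); treated prevalence is directly age/sex-standardized per
10,000.

## Worked example

Pooling a published-style regional grid — ward-admission coverage in four
regions of 16,196 / 9,462 / 934 / 5,096 prevalent patients at 14.2%, 12.4%,
12.2% and 8.6%:

```python
import pandas as pd
from mhqi import pool_proportions

regional = pd.DataFrame({
    "region": ["north-a", "north-b", "island", "centre"],
    "numerator": [0.142*16196, 0.124*9462, 0.122*934, 0.086*5096],
    "denominator": [16196, 9462, 934, 5096],
})
est = pool_proportions(regional, indicator_id="19", cohort="prevalent")
print(f"pooled {est.pooled_value:.1f}%  Q={est.q:.1f} df={est.df}  I2={est.i2:.0f}% ({est.band})")
```

prints

```
pooled 12.7%  Q=111.1 df=3  I2=97% (Considerable)
```

— 12.7% of prevalent patients were hospitalized at least once, with
considerable between-region heterogeneity.  End to end on synthetic data:

```python
from mhqi import RegionScenario, generate_region
from mhqi.pipeline import RunConfig, run_pipeline

res = generate_region(RegionScenario(region="demo", n_prevalent=2000, n_newly=150, seed=42))
report = run_pipeline(RunConfig(bundles=[]), stores=[res.store])
pooled = report.pooled.set_index(["indicator_id", "cohort"])
for ind in ["1", "14", "19", "24"]:
    print(ind, round(pooled.loc[(ind, "prevalent"), "pooled_value"], 1))
```

prints `1 93.8`, `14 49.9`, `19 13.0`, `24 61.0` — each within sampling
noise of the scenario's generating parameters (0.944, 0.491, 0.127, 0.612),
and the ground-truth ledger in `res.ledger` lets you verify every numerator
exactly.

The same pipeline runs from the shell:

```bash
mhqi synth --scenario examples/scenario_four_regions.yaml --out bundles/ --seed 1
mhqi run   --config examples/run.yaml --out report/
```

producing per-region cohort files, exclusion traces, the regional indicator
grid, the pooled grid with I² and rendered Markdown tables.

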