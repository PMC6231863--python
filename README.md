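# ctpa-yield

Computable-phenotype measurement of **CT pulmonary angiography (CTPA) yield**
in the emergency department, from structured EHR tables alone.

CTPA is the first-line imaging test for pulmonary embolism (PE), but it
carries real iatrogenic risk (contrast nephropathy, radiation). The **yield**
— the fraction of completed CTPA studies positive for PE —

```
yield = (# ED CTPA orders linked to an inpatient discharge diagnosis of PE)
        / (# completed ED CTPA orders, after exclusions)
```

is a standard proxy for the appropriateness of test ordering. Measuring it by
manual chart review is slow; this package implements the purely computerized
alternative: filter completed ED CTPA orders, exclude orders paired with a
same-day CTA of the abdomen/pelvis (the aortic-dissection protocol, not a PE
work-up), link each remaining order to an inpatient admission, and classify
it PE-positive iff the admission carries a PE discharge code — primary or
secondary — from explicit ICD-9-CM/ICD-10-CM code sets
(415.0, 415.11–415.13, 415.19; I26.0, I26.01, I26.02, I26.09, I26.9, I26.90,
I26.92, I26.99). Exact membership after normalization; no prefix expansion.

It is aimed at quality-improvement and clinical-informatics teams who have
flat exports of orders/encounters/admissions/diagnoses and want a
reproducible, auditable yield measure plus its validation statistics.

The package provides:

- **`ctpa_yield.io` / `ctpa_yield.model`** — a portable five-table CSV schema
  (imaging orders, ED encounters, inpatient admissions, discharge diagnoses,
  chart-review gold labels) with total row-level validation;
- **`ctpa_yield.pipeline`** — the filtering/exclusion/linkage/classification
  algorithm with full exclusion accounting, overall and per site;
- **`ctpa_yield.stats`** — validation against chart review: the 2×2 confusion
  table, Cohen's κ with large-sample SE and truncated 95% CI, McNemar's test
  (uncorrected, continuity-corrected, exact binomial), capture accuracy
  a/(a+c) and observed agreement (a+d)/n;
- **`ctpa_yield.synthetic`** — a seeded synthetic EHR cohort generator with
  exact count control, including a frozen two-site reference scenario, so the
  entire workflow runs without any real patient data.

The known failure mode is modeled explicitly: a PE-positive patient treated
and **discharged directly from the ED** acquires no inpatient discharge code
and is missed by admission-linked classification.

## Worked example

Generate the frozen two-site reference cohort, measure the yield, and
validate against the bundled gold labels:

```console
$ ctpa-yield simulate --preset reference --outdir demo/cohort
wrote 421 orders, 395 encounters, 220 admissions, 404 diagnoses, 349 labels to demo/cohort

$ ctpa-yield compute \
    --orders demo/cohort/orders.csv --encounters demo/cohort/ed_encounters.csv \
    --admissions demo/cohort/admissions.csv --diagnoses demo/cohort/diagnoses.csv \
    --classifications-csv demo/classifications.csv --out demo/report.json
27/349 analyzable CTPA orders PE-positive (yield 7.7%)

$ ctpa-yield validate \
    --classifications demo/classifications.csv \
    --gold-labels demo/cohort/gold_labels.csv --out demo/validation.json
kappa=0.98 ci95=(0.94, 1.0) mcnemar_p=0.317 capture=96.4%
```

Reading the numbers: of 375 raw completed ED CTPA orders, 26 (6.9%) were
excluded as same-day CTA abdomen/pelvis pairs, leaving 349 analyzable. The
computerized method classifies 27 as PE-positive (yield 7.7%; per site,
NSUH 18/203 = 8.9% and LIJMC 9/146 = 6.2% in `demo/report.json`). Chart
review marks 28 positive; the one discordant scan is the ED-discharge
patient, giving capture accuracy 27/28 = 96.4%, κ = 0.98 with 95% CI
(0.94, 1.00), and an uncorrected McNemar χ² = 1 with p = .32 — the computed
and chart-review yields do not differ significantly.

Custom cohorts come from a YAML spec (`ctpa-yield simulate --spec my.yaml
--seed 7 --outdir out/`); the same machinery is available as a library via
`generate_cohort`, `run_yield_pipeline`, and `compute_agreement`.

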