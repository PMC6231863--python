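# Methods

## The measurement model

The package measures emergency-department CTPA yield as a pure function of
four structured EHR tables. The unit of analysis is the **order**, not the
patient: two CTPAs for one patient count twice in the denominator, matching
how order-based utilization measures are reported.

1. **Cohort construction.** Keep imaging orders with `order_type = CTPA` and
   `status = COMPLETED`. Cancelled and discontinued orders never enter the
   denominator. The status column is taken at face value; whether "completed"
   means order completion or the final radiology read is an EHR-export
   convention the schema does not try to second-guess.
2. **Same-day CTA exclusion.** A completed CTPA is excluded when the *same
   patient* has a **completed** CTA of the abdomen and pelvis with an equal
   calendar date. Such pairs are ordered under the aortic-dissection
   protocol, not to evaluate PE, so they would otherwise dilute the yield.
   "Same day" is equal calendar date of the site-local wall-clock timestamp;
   timestamps are ISO-8601 strings with no timezone arithmetic, which is the
   plainest reading for single-site-local exports. The pairing is
   patient-level (not encounter-level), so a same-day CTA excludes all of
   that patient's same-day CTPAs. Cancelled/discontinued CTAs do not trigger
   exclusion — only studies actually performed reflect the dissection
   protocol.
3. **ED→inpatient linkage.** Each analyzable order is linked to at most one
   inpatient admission: first by the explicit `source_ed_encounter_id` key
   when the export carries one (two admissions claiming the same ED
   encounter is an integrity error); otherwise by falling back to the
   earliest same-patient admission whose admit time lies within
   `linkage_window_hours` (default **48 h**, chosen to span overnight ED
   boarding) after the order. Ties on admit time break deterministically by
   smallest admission id and are logged. No candidate at all is the
   ED-discharge case.
4. **PE classification.** An order is computed-PE-positive iff its linked
   admission carries at least one discharge diagnosis — primary **or**
   secondary — whose normalized code (uppercased, whitespace-stripped,
   dotless) is an exact member of the PE code set for its ICD version.
   Defaults: ICD-9-CM {415.0, 415.11, 415.12, 415.13, 415.19}, ICD-10-CM
   {I26.0, I26.01, I26.02, I26.09, I26.9, I26.90, I26.92, I26.99}. No
   hierarchical prefix expansion: the lists already enumerate the category
   headers (I26.0, I26.9) alongside their children, and expansion could
   over-match. The headers are non-billable in ICD-10-CM but are kept
   verbatim in case a source system emits them. Code sets are overridable
   via YAML for other phenotypes; the PE default is a frozen constant.
5. **Yield.** numerator / denominator over analyzable orders, overall and
   per site, with full accounting (raw completed, excluded, analyzable). A
   zero denominator yields an explicitly undefined fraction, never NaN or a
   crash.

## Validation statistics

Computed classifications are cross-tabulated against chart-review gold
labels into a 2×2 table (a = both positive, b = computed+/chart−,
c = computed−/chart+, d = both negative). Labels referring to unclassified
orders, and duplicates, are integrity errors — never silent drops.

- **Cohen's κ** = (p_o − p_e)/(1 − p_e) with p_o = (a+d)/n and
  p_e = [(a+b)(a+c) + (c+d)(b+d)]/n². The CI uses the large-sample standard
  error se = √[p_o(1−p_o)/(n(1−p_e)²)] with z = 1.96, truncated to [−1, 1]
  (the upper bound routinely truncates at 1 for near-perfect agreement).
- **McNemar's test** on the discordant cells: the default is the
  *uncorrected* χ² = (b−c)²/(b+c) against χ²(1). The continuity-corrected
  variant uses (max(|b−c|−1, 0))²/(b+c) — floored at zero so that b = c
  cannot produce a positive statistic — and the exact variant is the
  two-sided binomial test of b in b+c trials at probability ½. By
  convention, b+c = 0 gives p = 1 for every variant. The uncorrected
  default is deliberate: with a single discordant pair (b=0, c=1) it gives
  χ² = 1, p = .317, whereas correction or the exact test collapse to p = 1
  and cannot distinguish the paired yields at all at these discordance
  counts.
- **Capture accuracy** = a/(a+c), the fraction of chart-positive scans the
  computerized method identifies — operationally a sensitivity, reported
  under the label conventional for this measure. Observed agreement
  (a+d)/n is reported separately to avoid conflating the two. a+c = 0 is an
  explicit error, not NaN.

Display rounding (percentages to one decimal, κ to two) is applied only in
reports; underlying values keep full precision.

## The synthetic cohort generator

`generate_cohort` materializes the five tables from a `CohortSpec` of
per-site counts: completed CTPAs, cancelled/discontinued orders, same-day
CTA pairs, chart positives, ED-discharge positives (chart-positive but
never admitted, hence missed), unlinked negatives, plus the ICD-version and
primary/secondary rank mixes for the PE codes it plants. Every order
belongs to its own synthetic patient, so the pipeline's accounting,
numerator, and confusion table follow from the spec *exactly* — parameter
recovery by construction, which is what makes the generator usable as an
oracle for the pipeline. Infeasible specs (e.g., more positives than
analyzable orders) are rejected before generation. All randomness flows
from one seed through per-site `numpy` generators: the same seed gives
byte-identical CSVs; different seeds vary identifiers and timestamps but
never counts. Negative admissions receive filler codes (J18.9, N17.9, …)
asserted disjoint from the PE set.

The frozen **reference scenario** encodes a two-site, one-month-per-site
validation study: site NSUH (April 2016) with 229 raw completed CTPAs, 26
same-day exclusions → 203 analyzable, 19 chart positives, one of them
discharged from the ED; site LIJMC (November 2016) with 146 analyzable, 9
chart positives, all admitted. Overall: 375 raw, 26 excluded (6.9%), 349
analyzable, computed yield 27/349 = 7.7%, confusion table (27, 0, 1, 321).
Where the scenario is under-determined, the preset fixes conventions and
flags them in the generated `spec.json`: all 26 exclusions sit at NSUH;
cancelled/discontinued counts (12 and 8) are nominal and provably unable to
affect any result; all planted PE codes are ICD-10 (both study months
post-date the US ICD-10-CM transition of October 2015), with ICD-9 matching
exercised by the unit and property suites instead; the rank mix is 0.3
secondary (PE is usually the principal diagnosis when the ED admits for
it); roughly half of chart-negative patients are discharged home without an
admission, a realistic ED disposition pattern that the yield is insensitive
to.

What the generator does **not** emulate: demographics, vitals, note text,
coding noise (mis-coded or missing PE diagnoses), transfer patients, or
multiple CTPAs per patient (the default generator gives each order its own
patient; multi-order patients are constructed directly in tests where the
exclusion logic needs them). Passing on synthetic cohorts therefore
demonstrates the algorithm's internal correctness and its agreement
arithmetic, not robustness to real-world coding error.

## Numerical and design notes

- Problem sizes: the reference scenario (375 orders) runs in well under a
  second; property suites use cohorts of ≤ 30 orders across hundreds of
  random specs and 1,000 random 2×2 tables with n ≤ 500, keeping the whole
  suite in a few seconds.
- Determinism: pipeline results are invariant to input row order;
  classifications are emitted sorted by order id.
- The brute-force oracles in the tests (triple-loop yield recount, explicit
  expected-table κ, binomial-tail enumeration for exact McNemar) share no
  code with the implementation; statsmodels' `mcnemar` and scikit-learn's
  `cohen_kappa_score` provide additional independent cross-checks.
- One deliberate divergence from statsmodels: its continuity-corrected
  McNemar statistic is not floored at zero, so for b = c it reports a small
  positive χ²; this package floors the corrected statistic so perfect
  discordance symmetry always gives χ² = 0, p = 1.

## Limitations

- Classification requires an inpatient admission: PE-positive patients
  discharged directly from the ED are systematically missed (the reference
  scenario contains exactly one, reproducing the method's observed failure
  mode). Linking to ED/outpatient discharge diagnoses is out of scope.
- No distinction of acute vs chronic vs subsegmental PE — discharge codes
  do not carry it; chronic PE admissions would count as positive.
- No free-text processing of radiology reports, no live EHR connectivity,
  no HL7/FHIR ingestion: the schema is flat CSV by design, for portability
  and reproducibility.
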