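"""The yield-measurement algorithm: cohort construction, same-day CTA
abdomen/pelvis exclusion, ED-to-inpatient linkage, PE classification, and
yield computation with full exclusion accounting.

The unit of analysis is the ORDER, not the patient. The denominator is the
number of analyzable completed ED CTPA orders (completed minus same-day CTA
exclusions); the numerator is the number of those orders linked to an
inpatient admission carrying a PE discharge code, primary or secondary.
A PE-positive patient discharged directly from the ED has no linkable
admission and is classified negative — the method's known failure mode.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .codesets import DEFAULT_PE_CODESET, PECodeSet, is_pe_code
from .errors import IntegrityError
from .model import (
    DischargeDiagnosis,
    EDEncounter,
    ImagingOrder,
    InpatientAdmission,
    OrderStatus,
    OrderType,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SiteAccounting",
    "CohortAccounting",
    "OrderClassification",
    "SiteYield",
    "YieldResult",
    "select_completed_ed_ctpa",
    "exclude_same_day_cta",
    "link_order_to_admission",
    "classify_order_pe",
    "compute_yield",
    "run_yield_pipeline",
    "write_classifications",
    "read_classifications",
]


@dataclass(frozen=True)
class SiteAccounting:
    n_raw_completed_ctpa: int
    n_excluded_same_day_cta: int

    @property
    def n_analyzable(self) -> int:
        return self.n_raw_completed_ctpa - self.n_excluded_same_day_cta


@dataclass(frozen=True)
class CohortAccounting:
    """Order counts at each stage of cohort construction, overall and per site.

    Invariant: n_analyzable = n_raw_completed_ctpa - n_excluded_same_day_cta,
    and per-site counts sum to the overall totals.
    """

    n_raw_completed_ctpa: int
    n_excluded_same_day_cta: int
    per_site: Mapping[str, SiteAccounting] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_raw_completed_ctpa < 0 or self.n_excluded_same_day_cta < 0:
            raise ValueError("counts must be non-negative")
        if self.n_excluded_same_day_cta > self.n_raw_completed_ctpa:
            raise ValueError("excluded count exceeds raw count")
        if self.per_site:
            if sum(s.n_raw_completed_ctpa for s in self.per_site.values()) != self.n_raw_completed_ctpa:
                raise ValueError("per-site raw counts do not sum to overall")
            if sum(s.n_excluded_same_day_cta for s in self.per_site.values()) != self.n_excluded_same_day_cta:
                raise ValueError("per-site exclusion counts do not sum to overall")

    @property
    def n_analyzable(self) -> int:
        return self.n_raw_completed_ctpa - self.n_excluded_same_day_cta


@dataclass(frozen=True)
class OrderClassification:
    """The pipeline's verdict on one analyzable CTPA order."""

    order_id: str
    site_id: str
    linked_admission_id: Optional[str]
    computed_pe_positive: bool

    def __post_init__(self):
        if self.computed_pe_positive and self.linked_admission_id is None:
            raise ValueError("a PE-positive classification requires a linked admission")


@dataclass(frozen=True)
class SiteYield:
    numerator: int
    denominator: int

    @property
    def yield_fraction(self) -> Optional[float]:
        return self.numerator / self.denominator if self.denominator else None


@dataclass(frozen=True)
class YieldResult:
    """Numerator/denominator/fraction with full accounting.

    ``yield_fraction`` is None (undefined, not a crash) when the denominator
    is zero.
    """

    numerator: int
    denominator: int
    accounting: CohortAccounting
    per_site: Mapping[str, SiteYield] = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("need 0 <= numerator <= denominator")
        if self.per_site:
            if sum(s.numerator for s in self.per_site.values()) != self.numerator:
                raise ValueError("site numerators do not sum to overall")
            if sum(s.denominator for s in self.per_site.values()) != self.denominator:
                raise ValueError("site denominators do not sum to overall")

    @property
    def yield_fraction(self) -> Optional[float]:
        return self.numerator / self.denominator if self.denominator else None


def select_completed_ed_ctpa(orders: Sequence[ImagingOrder]) -> List[ImagingOrder]:
    """Retain CTPA orders with status COMPLETED; cancelled/discontinued and
    non-CTPA orders are dropped. Output order is stable."""
    return [
        o
        for o in orders
        if o.order_type is OrderType.CTPA and o.status is OrderStatus.COMPLETED
    ]


def exclude_same_day_cta(
    ctpa_orders: Sequence[ImagingOrder], all_orders: Sequence[ImagingOrder]
) -> Tuple[List[ImagingOrder], List[ImagingOrder]]:
    """Partition completed CTPA orders by the same-day dissection-protocol rule.

    A CTPA is excluded iff the same patient has a COMPLETED CTA of the
    abdomen and pelvis with an equal calendar date (such pairs are ordered
    under the aortic-dissection protocol, not to evaluate PE). Returns
    (retained, excluded).
    """
    cta_days = {
        (o.patient_id, o.order_datetime.date())
        for o in all_orders
        if o.order_type is OrderType.CTA_ABD_PELVIS
        and o.status is OrderStatus.COMPLETED
    }
    retained, excluded = [], []
    for o in ctpa_orders:
        if (o.patient_id, o.order_datetime.date()) in cta_days:
            excluded.append(o)
        else:
            retained.append(o)
    return retained, excluded


def index_admissions_by_encounter(
    admissions: Sequence[InpatientAdmission],
) -> Dict[str, InpatientAdmission]:
    """Index admissions by their explicit source ED encounter key.

    Raises IntegrityError if two admissions claim the same ED encounter.
    """
    index: Dict[str, InpatientAdmission] = {}
    for adm in admissions:
        key = adm.source_ed_encounter_id
        if key is None:
            continue
        if key in index:
            raise IntegrityError(
                f"admissions {index[key].admission_id} and {adm.admission_id} "
                f"share source_ed_encounter_id {key!r}"
            )
        index[key] = adm
    return index


def link_order_to_admission(
    order: ImagingOrder,
    encounters: Sequence[EDEncounter],
    admissions: Sequence[InpatientAdmission],
    linkage_window_hours: float = 48.0,
    _encounter_index: Optional[Dict[str, InpatientAdmission]] = None,
) -> Optional[str]:
    """Link an analyzable CTPA order to an inpatient admission, or None.

    Preference order:

    1. the admission whose ``source_ed_encounter_id`` equals the order's
       ED encounter (the explicit EHR join key);
    2. failing that, the earliest same-patient admission whose admit time
       falls in [order time, order time + ``linkage_window_hours``] — for
       exports lacking the explicit key;
    3. otherwise None: the ED-discharge case, no inpatient record to carry
       a discharge code.

    Ties on admit time break by smallest admission_id (logged).
    """
    index = (
        _encounter_index
        if _encounter_index is not None
        else index_admissions_by_encounter(admissions)
    )
    hit = index.get(order.ed_encounter_id)
    if hit is not None:
        return hit.admission_id

    window_end = order.order_datetime + pd.Timedelta(hours=linkage_window_hours)
    candidates = [
        a
        for a in admissions
        if a.patient_id == order.patient_id
        and order.order_datetime <= a.admit_datetime <= window_end
    ]
    if not candidates:
        return None
    earliest = min(candidates, key=lambda a: (a.admit_datetime, a.admission_id))
    if sum(1 for a in candidates if a.admit_datetime == earliest.admit_datetime) > 1:
        logger.warning(
            "order %s: tie on admit_datetime in linkage window; "
            "choosing smallest admission_id %s",
            order.order_id,
            earliest.admission_id,
        )
    return earliest.admission_id


def index_diagnoses(
    diagnoses: Sequence[DischargeDiagnosis],
) -> Dict[str, List[DischargeDiagnosis]]:
    index: Dict[str, List[DischargeDiagnosis]] = {}
    for d in diagnoses:
        index.setdefault(d.admission_id, []).append(d)
    return index


def classify_order_pe(
    order: ImagingOrder,
    linked_admission_id: Optional[str],
    diagnoses_by_admission: Mapping[str, Sequence[DischargeDiagnosis]],
    codeset: PECodeSet = DEFAULT_PE_CODESET,
) -> OrderClassification:
    """Positive iff the order has a linked admission and at least one of its
    discharge diagnoses, primary or secondary, is in the PE code set."""
    positive = False
    if linked_admission_id is not None:
        positive = any(
            is_pe_code(d.icd_code, d.icd_version, codeset)
            for d in diagnoses_by_admission.get(linked_admission_id, ())
        )
    return OrderClassification(
        order_id=order.order_id,
        site_id=order.site_id,
        linked_admission_id=linked_admission_id,
        computed_pe_positive=positive,
    )


def compute_yield(
    classifications: Sequence[OrderClassification], accounting: CohortAccounting
) -> YieldResult:
    """Assemble the YieldResult from per-order classifications.

    Requires exactly one classification per analyzable order. A zero
    denominator produces an undefined (None) yield_fraction.
    """
    if len(classifications) != accounting.n_analyzable:
        raise ValueError(
            f"{len(classifications)} classifications for "
            f"{accounting.n_analyzable} analyzable orders"
        )
    per_site: Dict[str, SiteYield] = {}
    if accounting.per_site:
        for site, acct in accounting.per_site.items():
            site_cls = [c for c in classifications if c.site_id == site]
            if len(site_cls) != acct.n_analyzable:
                raise ValueError(
                    f"site {site}: {len(site_cls)} classifications for "
                    f"{acct.n_analyzable} analyzable orders"
                )
            per_site[site] = SiteYield(
                numerator=sum(c.computed_pe_positive for c in site_cls),
                denominator=acct.n_analyzable,
            )
    return YieldResult(
        numerator=sum(c.computed_pe_positive for c in classifications),
        denominator=accounting.n_analyzable,
        accounting=accounting,
        per_site=per_site,
    )


def run_yield_pipeline(
    orders: Sequence[ImagingOrder],
    encounters: Sequence[EDEncounter],
    admissions: Sequence[InpatientAdmission],
    diagnoses: Sequence[DischargeDiagnosis],
    codeset: PECodeSet = DEFAULT_PE_CODESET,
    linkage_window_hours: float = 48.0,
) -> Tuple[YieldResult, List[OrderClassification]]:
    """Run the full algorithm end to end.

    Returns the YieldResult and the per-order classifications of every
    analyzable order, in a deterministic order (by order_id).
    """
    completed = select_completed_ed_ctpa(orders)
    retained, excluded = exclude_same_day_cta(completed, orders)

    sites = sorted({o.site_id for o in completed})
    per_site = {
        s: SiteAccounting(
            n_raw_completed_ctpa=sum(1 for o in completed if o.site_id == s),
            n_excluded_same_day_cta=sum(1 for o in excluded if o.site_id == s),
        )
        for s in sites
    }
    accounting = CohortAccounting(
        n_raw_completed_ctpa=len(completed),
        n_excluded_same_day_cta=len(excluded),
        per_site=per_site,
    )

    enc_index = index_admissions_by_encounter(admissions)
    diag_index = index_diagnoses(diagnoses)
    classifications = [
        classify_order_pe(
            o,
            link_order_to_admission(
                o, encounters, admissions, linkage_window_hours, enc_index
            ),
            diag_index,
            codeset,
        )
        for o in sorted(retained, key=lambda o: o.order_id)
    ]
    return compute_yield(classifications, accounting), classifications


_CLS_COLUMNS = ["order_id", "site_id", "linked_admission_id", "computed_pe_positive"]


def write_classifications(
    classifications: Sequence[OrderClassification], path: Union[str, Path]
) -> None:
    rows = [
        {
            "order_id": c.order_id,
            "site_id": c.site_id,
            "linked_admission_id": c.linked_admission_id or "",
            "computed_pe_positive": "true" if c.computed_pe_positive else "false",
        }
        for c in classifications
    ]
    pd.DataFrame(rows, columns=_CLS_COLUMNS).to_csv(path, index=False)


def read_classifications(path: Union[str, Path]) -> List[OrderClassification]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        OrderClassification(
            order_id=r["order_id"],
            site_id=r["site_id"],
            linked_admission_id=r["linked_admission_id"] or None,
            computed_pe_positive=r["computed_pe_positive"].strip().lower()
            in {"true", "1", "yes"},
        )
        for _, r in df.iterrows()
    ]
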