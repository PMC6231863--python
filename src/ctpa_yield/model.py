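"""EHR data model: typed records for imaging orders, ED encounters,
inpatient admissions, discharge diagnoses, and chart-review labels.

Timestamps are ISO-8601 wall-clock times local to the ordering site; no
timezone arithmetic is performed. "Same day" downstream means equal calendar
date.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from enum import Enum
from typing import Optional


class OrderType(Enum):
    CTPA = "CTPA"
    CTA_ABD_PELVIS = "CTA_ABD_PELVIS"
    OTHER = "OTHER"


class OrderStatus(Enum):
    COMPLETED = "COMPLETED"
    CANCELLED = "CANCELLED"
    DISCONTINUED = "DISCONTINUED"


class Disposition(Enum):
    ADMITTED = "ADMITTED"
    DISCHARGED_FROM_ED = "DISCHARGED_FROM_ED"


class ICDVersion(Enum):
    ICD9 = "ICD9"
    ICD10 = "ICD10"


class DiagnosisRank(Enum):
    PRIMARY = "PRIMARY"
    SECONDARY = "SECONDARY"


@dataclass(frozen=True)
class ImagingOrder:
    """One imaging order event placed during an ED course."""

    order_id: str
    patient_id: str
    ed_encounter_id: str
    order_type: OrderType
    status: OrderStatus
    order_datetime: datetime
    site_id: str


@dataclass(frozen=True)
class EDEncounter:
    ed_encounter_id: str
    patient_id: str
    arrival_datetime: datetime
    disposition: Disposition


@dataclass(frozen=True)
class InpatientAdmission:
    """Inpatient stay; ``source_ed_encounter_id`` is the explicit ED-to-
    inpatient link key when the export carries one, else ``None``."""

    admission_id: str
    patient_id: str
    source_ed_encounter_id: Optional[str]
    admit_datetime: datetime
    discharge_datetime: datetime

    def __post_init__(self):
        if self.admit_datetime > self.discharge_datetime:
            raise ValueError(
                f"admission {self.admission_id}: admit_datetime after "
                f"discharge_datetime"
            )


@dataclass(frozen=True)
class DischargeDiagnosis:
    """A coded discharge diagnosis on an inpatient admission; both PRIMARY
    and SECONDARY ranks count toward PE classification."""

    admission_id: str
    icd_code: str
    icd_version: ICDVersion
    rank: DiagnosisRank

    def __post_init__(self):
        if not self.icd_code.strip():
            raise ValueError("icd_code must be non-empty")


@dataclass(frozen=True)
class GoldStandardLabel:
    """Chart-review adjudication of one CTPA order (the gold standard)."""

    order_id: str
    chart_review_pe_positive: bool
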