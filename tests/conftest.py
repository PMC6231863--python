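from datetime import datetime

import pytest

from ctpa_yield.model import (
    DiagnosisRank,
    DischargeDiagnosis,
    Disposition,
    EDEncounter,
    ICDVersion,
    ImagingOrder,
    InpatientAdmission,
    OrderStatus,
    OrderType,
)


def make_order(
    order_id="O1",
    patient_id="P1",
    ed_encounter_id="E1",
    order_type=OrderType.CTPA,
    status=OrderStatus.COMPLETED,
    order_datetime=datetime(2016, 4, 3, 10, 0),
    site_id="A",
):
    return ImagingOrder(
        order_id, patient_id, ed_encounter_id, order_type, status,
        order_datetime, site_id,
    )


def make_encounter(
    ed_encounter_id="E1",
    patient_id="P1",
    arrival=datetime(2016, 4, 3, 8, 0),
    disposition=Disposition.ADMITTED,
):
    return EDEncounter(ed_encounter_id, patient_id, arrival, disposition)


def make_admission(
    admission_id="A1",
    patient_id="P1",
    source_ed_encounter_id="E1",
    admit=datetime(2016, 4, 3, 16, 0),
    discharge=datetime(2016, 4, 7, 12, 0),
):
    return InpatientAdmission(
        admission_id, patient_id, source_ed_encounter_id, admit, discharge
    )


def make_diagnosis(
    admission_id="A1",
    icd_code="I26.99",
    icd_version=ICDVersion.ICD10,
    rank=DiagnosisRank.PRIMARY,
):
    return DischargeDiagnosis(admission_id, icd_code, icd_version, rank)


@pytest.fixture
def pe_admission_set():
    """One admitted PE-positive patient: order + encounter + admission + dx."""
    return (
        [make_order()],
        [make_encounter()],
        [make_admission()],
        [make_diagnosis(rank=DiagnosisRank.SECONDARY)],
    )
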