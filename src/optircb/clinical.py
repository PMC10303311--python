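"""Reference residual-disease summaries of the 15-patient monitoring study.

These small tables are the published per-treatment AUC summaries and RCB
annotations of the neoadjuvant-chemotherapy cohort the method was
developed on. They let the scoring stages (oRCB, pRCB mapping, class
assignment) be exercised and cross-checked without any optical raw data:
per-treatment residual-disease errors feed ``compute_orcb`` directly, and
the patients with a pathologically graded RCB provide the training pairs
for the oRCB-to-pRCB regression.

Treatment ids: 0 = pretreatment, k = post-treatment cycle k,
8 = post-chemotherapy follow-up scan.
"""

from __future__ import annotations

from dataclasses import dataclass

from .burden import TreatmentSummary

__all__ = [
    "ClinicalRecord",
    "TREATMENT_RECORDS",
    "FULL_ERROR_SERIES",
    "KNOWN_PRCB",
    "REFERENCE_ORCB",
    "REFERENCE_PREDICTIONS",
    "CONFIDENCE_ROWS",
    "EXCLUDED_PATIENTS",
    "treatment_summaries",
    "known_training_pairs",
]

POST_CHEMO = 8


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient-treatment row of the cohort summary table."""

    patient_id: int
    treatment_id: int
    total_unhealthy: float
    total_healthy: float
    total_error: float


#: The per-patient extreme-treatment rows (the treatments attaining the
#: largest and smallest residual-disease error) of the cohort table.
TREATMENT_RECORDS: tuple[ClinicalRecord, ...] = (
    ClinicalRecord(10, 0, 1914.8, 1839.3, 75.45),
    ClinicalRecord(10, 7, 1882.9, 1842.4, 40.40),
    ClinicalRecord(12, 0, 1680.1, 1657.1, 22.96),
    ClinicalRecord(12, 5, 1652.1, 1657.1, 0.00),
    ClinicalRecord(13, 0, 1902.9, 1838.4, 64.56),
    ClinicalRecord(13, 6, 1821.5, 1838.4, 0.00),
    ClinicalRecord(14, 0, 1657.7, 1614.1, 43.64),
    ClinicalRecord(14, 7, 1630.4, 1614.1, 16.31),
    ClinicalRecord(15, 0, 1707.1, 1601.6, 105.51),
    ClinicalRecord(15, 7, 1630.0, 1602.8, 27.176),
    ClinicalRecord(16, 0, 2144.2, 1983.3, 160.95),
    ClinicalRecord(16, 3, 2122.5, 1991.6, 130.92),
    ClinicalRecord(17, 1, 2035.0, 1981.5, 53.463),
    ClinicalRecord(17, 7, 1995.6, 1990.9, 4.679),
    ClinicalRecord(19, 0, 1860.5, 1815.4, 45.15),
    ClinicalRecord(19, 5, 1825.6, 1815.4, 10.25),
    ClinicalRecord(21, 4, 1603.5, 1588.8, 14.69),
    ClinicalRecord(21, 7, 1615.5, 1607.6, 7.96),
    ClinicalRecord(22, 1, 2034.5, 1995.8, 38.72),
    ClinicalRecord(22, 6, 2014.5, 2005.4, 9.09),
    ClinicalRecord(26, 1, 1627.3, 1594.0, 33.34),
    ClinicalRecord(26, 6, 1627.2, 1605.7, 21.46),
    ClinicalRecord(29, 2, 2074.2, 2073.3, 0.89),
    ClinicalRecord(29, POST_CHEMO, 2028.0, 2054.8, 0.00),
    ClinicalRecord(30, 0, 2018.2, 1983.3, 34.91),
    ClinicalRecord(30, 5, 1976.6, 1975.7, 0.93),
    ClinicalRecord(31, 0, 2025.3, 1999.3, 25.99),
    ClinicalRecord(31, 5, 2001.1, 2015.3, 0.00),
)

#: Patients excluded from scoring for lack of usable scans.
EXCLUDED_PATIENTS: tuple[int, ...] = (18,)

#: Complete per-treatment error series of the three narrated patients
#: (treatment id -> residual-disease error); missing scans are absent.
FULL_ERROR_SERIES: dict[int, dict[int, float]] = {
    12: {0: 22.96, 1: 12.04, 2: 22.17, 3: 9.98, 4: 0.00, 5: 0.00},
    13: {0: 64.56, 1: 90.88, 2: 57.77, 3: 30.63, 4: 5.89, 5: 0.00, 6: 0.00},
    26: {0: 39.97, 1: 34.34, 6: 21.46},
}

#: Pathologically graded RCB index and class, where surgery provided one.
KNOWN_PRCB: dict[int, tuple[float, str]] = {
    10: (3.93, "RCB-III"),
    12: (0.00, "RCB-0"),
    13: (0.00, "RCB-0"),
    14: (2.51, "RCB-II"),
    15: (2.18, "RCB-II"),
    19: (1.60, "RCB-II"),
    29: (0.00, "RCB-0"),
}

#: Reported oRCB values (percent) per patient.
REFERENCE_ORCB: dict[int, float] = {
    10: 53.54, 12: 0.00, 13: 0.00, 14: 37.37, 15: 25.75, 16: 81.34,
    17: 8.75, 19: 22.70, 21: 54.15, 22: 23.47, 26: 64.37, 29: 0.00,
    30: 2.67, 31: 0.00,
}

#: Reported predicted pRCB index and class for the ungraded patients.
REFERENCE_PREDICTIONS: dict[int, tuple[float, str]] = {
    16: (5.88, "RCB-III"),
    17: (0.67, "RCB-I"),
    21: (3.93, "RCB-III"),
    22: (1.73, "RCB-II"),
    26: (4.66, "RCB-III"),
    30: (0.23, "RCB-I"),
    31: (0.00, "RCB-0"),
}

#: Reported (oRCB, pRCB, lower, upper) confidence rows for the ungraded
#: patients, keyed by patient id.
CONFIDENCE_ROWS: dict[int, tuple[float, float, float, float]] = {
    16: (81.34, 5.88, 3.70, 8.06),
    17: (8.75, 0.67, -1.51, 2.85),
    21: (54.15, 3.93, 1.75, 6.11),
    22: (23.47, 1.73, -0.45, 3.91),
    26: (64.37, 4.66, 2.49, 6.84),
    30: (2.67, 0.23, -1.94, 2.41),
    31: (0.00, 0.00, -2.13, 2.22),
}


def treatment_summaries(patient_id: int) -> list[TreatmentSummary]:
    """The recorded per-treatment summaries of one patient."""
    rows = [r for r in TREATMENT_RECORDS if r.patient_id == patient_id]
    if not rows:
        raise KeyError(f"no recorded treatments for patient {patient_id}")
    return [
        TreatmentSummary(
            treatment_id=r.treatment_id,
            total_unhealthy=r.total_unhealthy,
            total_healthy=r.total_healthy,
            total_error=r.total_error,
        )
        for r in rows
    ]


def known_training_pairs() -> list[tuple[float, float]]:
    """(oRCB, known pRCB) pairs of the pathologically graded patients."""
    return [
        (REFERENCE_ORCB[pid], KNOWN_PRCB[pid][0]) for pid in sorted(KNOWN_PRCB)
    ]
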