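"""Reference per-PEEP elastance summaries for ten ALI/ARDS patients.

These tables transcribe published per-patient, per-PEEP summary values from a
clinical recruitment-manoeuvre study (10 sedated, paralysed ALI/ARDS patients
ventilated in volume control, PEEP raised in 5 cmH2O steps from ZEEP):
constant lung elastance ``e_lung`` (cmH2O/l), the per-level median dynamic
elastance ``edrs_median`` (cmH2O/l), the dynamic-elastance time integral
``edrs_area`` (cmH2O.s/l), the clinically set PEEP, and a COPD flag.

The raw waveforms behind these summaries are not publicly available, so the
tables serve as pre-aggregated inputs for demonstrating and validating the
selection rules.  Note the titration grids are data, not assumption: several
patients stop on off-grid levels (e.g. PEEP 16, 22, 27, 28) where the
peak-pressure limit was reached.
"""

from __future__ import annotations

import pandas as pd

from .metrics import TitrationSummary

__all__ = [
    "PATIENT_TABLES",
    "COPD_PATIENTS",
    "CLINICAL_PEEP",
    "reference_table",
    "reference_titration",
    "zeep_edrs_medians",
]

#: per-patient titration grids and metric rows (ordered by increasing PEEP)
PATIENT_TABLES: dict[int, dict] = {
    1: {
        "peep": [0, 5, 10, 15, 20, 25, 27],
        "e_lung": [53.8, 47.0, 41.2, 32.8, 32.8, 32.1, 32.2],
        "edrs_median": [63.1, 53.8, 43.6, 35.0, 33.4, 31.1, 32.2],
        "edrs_area": [84.6, 49.5, 37.1, 28.9, 26.6, 25.7, 25.7],
    },
    2: {
        "peep": [0, 5, 10, 15, 20, 22],
        "e_lung": [27.7, 25.3, 22.8, 22.3, 22.6, 23.1],
        "edrs_median": [30.8, 26.4, 23.1, 22.1, 22.5, 23.1],
        "edrs_area": [34.0, 24.8, 21.0, 20.2, 20.3, 20.7],
    },
    3: {
        "peep": [0, 5, 10, 15, 20, 25, 28],
        "e_lung": [24.0, 21.6, 18.3, 17.3, 17.4, 18.1, 19.1],
        "edrs_median": [26.9, 22.1, 18.3, 17.3, 17.5, 17.8, 19.2],
        "edrs_area": [37.7, 27.6, 22.2, 20.8, 19.1, 19.7, 18.9],
    },
    4: {
        "peep": [0, 5, 10, 15, 20, 25, 30],
        "e_lung": [60.2, 59.7, 50.1, 35.1, 27.8, 25.3, 22.5],
        "edrs_median": [73.2, 70.4, 54.5, 36.8, 28.5, 25.9, 23.1],
        "edrs_area": [102.2, 91.2, 61.7, 37.9, 31.7, 48.1, 47.5],
    },
    5: {
        "peep": [0, 5, 10, 15, 20, 25],
        "e_lung": [87.4, 84.0, 81.2, 74.3, 65.7, 53.1],
        "edrs_median": [105.7, 97.8, 89.3, 79.4, 67.3, 52.3],
        "edrs_area": [118.7, 99.9, 89.1, 70.6, 75.7, 42.9],
    },
    6: {
        "peep": [0, 5, 10, 15, 20, 25],
        "e_lung": [27.1, 25.5, 22.8, 21.6, 21.8, 23.4],
        "edrs_median": [30.4, 26.2, 23.3, 21.6, 21.8, 23.3],
        "edrs_area": [29.4, 23.8, 20.8, 21.6, 19.5, 20.8],
    },
    7: {
        "peep": [0, 5, 10, 15, 16],
        "e_lung": [47.7, 42.5, 45.5, 55.7, 55.3],
        "edrs_median": [49.3, 42.2, 44.3, 53.6, 52.4],
        "edrs_area": [37.6, 33.8, 31.3, 37.9, 32.1],
    },
    8: {
        "peep": [0, 5, 10, 15, 20, 25, 30],
        "e_lung": [41.7, 35.5, 31.2, 28.7, 27.5, 26.6, 27.0],
        "edrs_median": [45.7, 37.2, 31.8, 28.8, 27.4, 26.8, 27.0],
        "edrs_area": [55.1, 38.5, 32.0, 29.0, 27.5, 24.1, 24.3],
    },
    9: {
        "peep": [0, 5, 10, 15, 20, 25, 30],
        "e_lung": [51.3, 39.1, 38.2, 31.1, 28.2, 26.2, 26.1],
        "edrs_median": [58.1, 40.5, 39.9, 31.2, 28.3, 26.3, 26.2],
        "edrs_area": [106.5, 55.2, 51.3, 38.3, 34.1, 31.6, 31.3],
    },
    10: {
        "peep": [0, 5, 10, 15, 20, 25, 27],
        "e_lung": [51.0, 44.1, 39.2, 35.8, 33.9, 34.0, 34.2],
        "edrs_median": [54.4, 45.2, 39.4, 35.9, 33.9, 33.9, 33.9],
        "edrs_area": [74.7, 52.6, 44.0, 39.5, 37.3, 37.2, 37.3],
    },
}

#: patients with COPD (or equivalent clinical features)
COPD_PATIENTS = frozenset({1, 4, 5, 9, 10})

#: PEEP (cmH2O) chosen clinically during the same titrations
CLINICAL_PEEP: dict[int, float] = {
    1: 10, 2: 12, 3: 10, 4: 10, 5: 12, 6: 11, 7: 7.5, 8: 12, 9: 10, 10: 10,
}


def reference_table() -> pd.DataFrame:
    """All patients in long format: patient, peep, e_lung, edrs_median, edrs_area."""
    rows = []
    for pid, tab in PATIENT_TABLES.items():
        for i, peep in enumerate(tab["peep"]):
            rows.append(
                {
                    "patient": pid,
                    "peep": peep,
                    "e_lung": tab["e_lung"][i],
                    "edrs_median": tab["edrs_median"][i],
                    "edrs_area": tab["edrs_area"][i],
                }
            )
    return pd.DataFrame(rows)


def reference_titration(patient: int) -> TitrationSummary:
    """One patient's table as a TitrationSummary ready for the selection rules."""
    tab = PATIENT_TABLES[patient]
    return TitrationSummary.from_dataframe(pd.DataFrame(tab), patient_id=str(patient))


def zeep_edrs_medians(group: str = "all") -> list[float]:
    """Per-patient median dynamic elastance at ZEEP (cmH2O/l).

    ``group`` is ``"all"``, ``"copd"`` or ``"non_copd"``.
    """
    if group == "all":
        ids = sorted(PATIENT_TABLES)
    elif group == "copd":
        ids = sorted(COPD_PATIENTS)
    elif group == "non_copd":
        ids = sorted(set(PATIENT_TABLES) - COPD_PATIENTS)
    else:
        raise ValueError("group must be 'all', 'copd' or 'non_copd'")
    return [PATIENT_TABLES[p]["edrs_median"][0] for p in ids]
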