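"""Shared fixtures: a hand-built six-patient screening table set and a small
generated cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nedose.simulate import CohortConfig, SyntheticTables, generate_cohort

T0 = pd.Timestamp("2023-03-01 00:00:00")


def _hours(h: float) -> pd.Timedelta:
    return pd.Timedelta(hours=h)


def toy_patient(
    pid: int,
    ne_offset_h: float = 4.0,
    weight: float | None = 80.0,
    ne_rates: tuple[float, float] = (0.2, 0.4),
    lactate: float = 3.2,
    sofa: int = 7,
    death: int = 0,
) -> dict[str, list[dict]]:
    """Rows for one patient across the five tables.

    Defaults pass every screening criterion: infection pair at T0, SOFA 7,
    norepinephrine from T0+ne_offset_h with a 2 h segment at ne_rates[0] then
    1 h at ne_rates[1], lactate near NE start.
    """
    t_ne = T0 + _hours(ne_offset_h)
    return {
        "patients": [
            {"patient_id": pid, "age": 60, "weight_kg": weight,
             "admission_time": T0 - _hours(6), "death_28d": death}
        ],
        "infection_events": [
            {"patient_id": pid, "event_type": "culture", "charttime": T0},
            {"patient_id": pid, "event_type": "antibiotic", "charttime": T0 + _hours(2)},
        ],
        "sofa": [{"patient_id": pid, "charttime": T0 + _hours(1), "sofa": sofa}],
        "labs": [
            {"patient_id": pid, "charttime": t_ne + pd.Timedelta(minutes=10),
             "lactate_mmol_l": lactate}
        ],
        "infusion_events": [
            {"patient_id": pid, "drug": "norepinephrine", "start_time": t_ne,
             "end_time": t_ne + _hours(2), "rate": ne_rates[0], "rate_unit": "ug/kg/min"},
            {"patient_id": pid, "drug": "norepinephrine", "start_time": t_ne + _hours(2),
             "end_time": t_ne + _hours(3), "rate": ne_rates[1], "rate_unit": "ug/kg/min"},
        ],
    }


def merge_toys(*patients: dict) -> dict[str, pd.DataFrame]:
    tables: dict[str, list] = {}
    for p in patients:
        for name, rows in p.items():
            tables.setdefault(name, []).extend(rows)
    return {name: pd.DataFrame(rows) for name, rows in tables.items()}


@pytest.fixture
def six_patient_tables() -> dict[str, pd.DataFrame]:
    """Three passers plus one failure each of: eligibility window, missing
    demographics, and no valid dose after outlier removal."""
    return merge_toys(
        toy_patient(1, death=1),
        toy_patient(2, ne_offset_h=-13.0),           # NE starts 13 h before sepsis
        toy_patient(3, weight=np.nan),               # missing key demographics
        toy_patient(4, ne_rates=(7.0, 7.0)),         # every record an outlier
        toy_patient(5, ne_rates=(0.1, 0.3)),
        toy_patient(6, ne_rates=(0.05, 0.15), death=1),
    )


@pytest.fixture(scope="session")
def small_tables() -> SyntheticTables:
    return generate_cohort(CohortConfig(n_patients=400, seed=7))


@pytest.fixture(scope="session")
def small_cohort(small_tables) -> pd.DataFrame:
    from nedose.screen import apply_screen

    return apply_screen(small_tables).cohort
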