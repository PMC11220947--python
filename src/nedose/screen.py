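"""Sepsis-3 septic-shock eligibility screen over the five event tables.

Septic shock is operationalised the Sepsis-3 way: suspicion of infection
(a culture/antibiotic pair within configurable pairing windows), organ
dysfunction (SOFA >= 2 at or after the suspicion time), vasopressor
requirement (any norepinephrine infusion), and hyperlactataemia
(lactate >= 2 mmol/L at vasopressor initiation).  On top of eligibility,
three exclusions apply: norepinephrine starting more than 12 h before or 72 h
after the sepsis diagnosis, missing key demographics, and absence of valid
norepinephrine dose values after outlier removal.

Criteria are applied in a fixed, documented order (age, infection, SOFA,
NE use, lactate, window, demographics, dose availability); each excluded
patient is charged to the FIRST criterion they fail, so the exclusion ledger
is reproducible and conserves counts: input n = retained + sum(exclusions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import infusions
from .formulations import NeEquivalentWeights
from .simulate import SyntheticTables

__all__ = ["ScreenCriteria", "ScreenResult", "suspected_infection_time",
           "septic_shock_onset", "apply_screen", "EXCLUSION_ORDER"]

EXCLUSION_ORDER = (
    "age", "infection", "sofa", "ne_use", "lactate", "window", "demographics", "dose",
)


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds and windows of the eligibility screen (all configurable)."""

    min_age: float = 18.0
    sofa_min: int = 2
    lactate_min: float = 2.0  # mmol/L at vasopressor initiation
    ne_window_before_h: float = 12.0  # NE may start up to this long before diagnosis
    ne_window_after_h: float = 72.0  # ... or this long after
    abx_after_culture_h: float = 72.0  # antibiotic within this window after culture
    culture_after_abx_h: float = 24.0  # culture within this window after antibiotic
    lactate_lookaround_h: float = 6.0  # nearest lactate within +/- this of NE start

    def __post_init__(self) -> None:
        for name in ("ne_window_before_h", "ne_window_after_h", "abx_after_culture_h",
                     "culture_after_abx_h", "lactate_lookaround_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lactate_min <= 0:
            raise ValueError("lactate_min must be positive")


@dataclass
class ScreenResult:
    cohort: pd.DataFrame
    ledger: dict[str, int]

    @property
    def n_input(self) -> int:
        return len(self.cohort) + sum(self.ledger.values())


def suspected_infection_time(
    culture_times: Sequence[pd.Timestamp],
    antibiotic_times: Sequence[pd.Timestamp],
    criteria: ScreenCriteria = ScreenCriteria(),
) -> pd.Timestamp | None:
    """Earliest time of a qualifying culture/antibiotic pair, or None.

    A pair qualifies when the antibiotic starts within ``abx_after_culture_h``
    after the culture, or the culture is drawn within ``culture_after_abx_h``
    after the antibiotic; the pair's time is the earlier of the two events.
    """
    best = None
    for c in culture_times:
        for a in antibiotic_times:
            delta_h = (a - c) / pd.Timedelta(hours=1)
            if -criteria.culture_after_abx_h <= delta_h <= criteria.abx_after_culture_h:
                t = min(c, a)
                best = t if best is None else min(best, t)
    return best


def septic_shock_onset(
    ne_start: pd.Timestamp,
    t_suspicion: pd.Timestamp,
    sofa: pd.DataFrame,
    labs: pd.DataFrame,
    criteria: ScreenCriteria = ScreenCriteria(),
) -> pd.Timestamp | None:
    """NE start time if shock criteria hold there, else None.

    Requires a SOFA record >= ``sofa_min`` at/after the suspicion time and the
    lactate measurement nearest NE initiation (within the lookaround window)
    to be >= ``lactate_min``.
    """
    ok_sofa = sofa[(sofa["charttime"] >= t_suspicion) & (sofa["sofa"] >= criteria.sofa_min)]
    if ok_sofa.empty:
        return None
    lac = _lactate_at(labs, ne_start, criteria)
    if lac is None or lac < criteria.lactate_min:
        return None
    return ne_start


def _lactate_at(labs: pd.DataFrame, t: pd.Timestamp, criteria: ScreenCriteria) -> float | None:
    if labs.empty:
        return None
    dist = np.abs((labs["charttime"].to_numpy() - np.datetime64(t)) / np.timedelta64(60, "s"))
    mask = dist <= criteria.lactate_lookaround_h * 60.0
    if not mask.any():
        return None
    vals = labs["lactate_mmol_l"].to_numpy(float)
    return float(vals[mask][np.argmin(dist[mask])])


_REQUIRED = {
    "patients": {"patient_id", "age", "weight_kg", "admission_time", "death_28d"},
    "infusion_events": {"patient_id", "drug", "start_time", "end_time", "rate", "rate_unit"},
    "labs": {"patient_id", "charttime", "lactate_mmol_l"},
    "infection_events": {"patient_id", "event_type", "charttime"},
    "sofa": {"patient_id", "charttime", "sofa"},
}


def _validate_tables(frames: Mapping[str, pd.DataFrame]) -> None:
    for name, cols in _REQUIRED.items():
        if name not in frames:
            raise ValueError(f"missing input table {name!r}")
        missing = cols - set(frames[name].columns)
        if missing:
            raise ValueError(f"table {name!r} lacks required columns {sorted(missing)}")


def apply_screen(
    tables: SyntheticTables | Mapping[str, pd.DataFrame],
    criteria: ScreenCriteria = ScreenCriteria(),
    outlier_ceiling: float = infusions.DEFAULT_OUTLIER_CEILING,
    nee_weights: NeEquivalentWeights | None = None,
) -> ScreenResult:
    """Apply the full eligibility screen and extract per-patient dose variables.

    Returns the analysis cohort (one row per retained patient with diagnosis
    and stability-filtered peak doses) and the ordered exclusion ledger.
    """
    frames = tables.as_dict() if isinstance(tables, SyntheticTables) else dict(tables)
    _validate_tables(frames)

    infx_by = dict(tuple(frames["infection_events"].groupby("patient_id", sort=False)))
    sofa_by = dict(tuple(frames["sofa"].groupby("patient_id", sort=False)))
    labs_by = dict(tuple(frames["labs"].groupby("patient_id", sort=False)))
    inf_by = dict(tuple(frames["infusion_events"].groupby("patient_id", sort=False)))
    empty = {n: frames[n].iloc[0:0] for n in frames}

    ledger = {k: 0 for k in EXCLUSION_ORDER}
    rows = []
    for pat in frames["patients"].itertuples(index=False):
        pid = pat.patient_id
        if not (np.isfinite(pat.age) and pat.age >= criteria.min_age):
            ledger["age"] += 1
            continue
        infx = infx_by.get(pid, empty["infection_events"])
        t_susp = suspected_infection_time(
            infx.loc[infx["event_type"] == "culture", "charttime"],
            infx.loc[infx["event_type"] == "antibiotic", "charttime"],
            criteria,
        )
        if t_susp is None:
            ledger["infection"] += 1
            continue
        sofa = sofa_by.get(pid, empty["sofa"])
        sofa_times = sofa["charttime"].to_numpy()
        sofa_scores = sofa["sofa"].to_numpy()
        after = sofa_times >= np.datetime64(t_susp)
        if not np.any(after & (sofa_scores >= criteria.sofa_min)):
            ledger["sofa"] += 1
            continue
        ev = inf_by.get(pid, empty["infusion_events"])
        ne_mask = ev["drug"].to_numpy() == infusions.NE_DRUG
        if not ne_mask.any():
            ledger["ne_use"] += 1
            continue
        ne_start = pd.Timestamp(ev["start_time"].to_numpy()[ne_mask].min())
        labs = labs_by.get(pid, empty["labs"])
        lac = _lactate_at(labs, ne_start, criteria)
        if lac is None or lac < criteria.lactate_min:
            ledger["lactate"] += 1
            continue
        offset_h = (ne_start - t_susp) / pd.Timedelta(hours=1)
        if not (-criteria.ne_window_before_h <= offset_h <= criteria.ne_window_after_h):
            ledger["window"] += 1
            continue
        weight = pat.weight_kg
        if weight is None or not np.isfinite(weight) or weight <= 0:
            ledger["demographics"] += 1
            continue
        summ = infusions.summarize_patient(
            ev, pid, ne_start, weight, nee_weights, outlier_ceiling
        )
        if summ.no_stable_peak or summ.peak_dose_24h is None or summ.diagnosis_dose is None:
            ledger["dose"] += 1
            continue
        sofa_at = sofa_scores[after][0]
        rows.append(
            {
                "patient_id": pid,
                "t_sepsis": t_susp,
                "t_shock": ne_start,
                "age": pat.age,
                "weight_kg": weight,
                "sofa": int(sofa_at),
                "lactate_at_diagnosis": lac,
                "diagnosis_dose": float(summ.diagnosis_dose),
                "peak_dose_24h": float(summ.peak_dose_24h),
                "peak_ne_equivalent_24h": float(summ.peak_ne_equivalent_24h),
                "death_28d": int(pat.death_28d),
                "outlier_excluded_records": int(summ.outlier_excluded_records),
            }
        )
    cohort = pd.DataFrame(rows)
    return ScreenResult(cohort, ledger)
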