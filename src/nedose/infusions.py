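"""Turn raw vasopressor infusion event streams into patient-level dose variables.

An infusion stream is a sequence of rate segments (start, end, rate): the pump
runs at ``rate`` on the right-open interval ``[start, end)``.  Gaps between
segments mean the infusion is off (rate 0).  From such a stream this module
extracts the three dose variables of the analysis:

* the *peak dose* in the 24 h after shock diagnosis, filtered for stability —
  the highest rate that stays within a 10% band for at least 5 contiguous
  minutes, so transient pump spikes and registry glitches are not mistaken for
  a clinical peak;
* the *diagnosis dose* — the rate started or titrated closest in time to the
  shock diagnosis;
* the *peak norepinephrine-equivalent rate* across all concurrent vasopressors.

Rates are weight-normalised to ug/kg/min before any of this; registry-error
outliers above a configurable ceiling are removed first and counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formulations import NeEquivalentWeights, default_nee_weights

__all__ = [
    "Segment",
    "DoseSummary",
    "weight_normalize",
    "exclude_outlier_rates",
    "stable_peak_dose",
    "diagnosis_dose",
    "peak_ne_equivalent",
    "dose_summaries",
    "DEFAULT_OUTLIER_CEILING",
    "PEAK_WINDOW_MINUTES",
]

# Registry-error ceiling in ug/kg/min base molecule.  Clinical NE doses above
# 5 ug/kg/min are not plausible sustained prescriptions; the ceiling is
# configurable everywhere it is used.
DEFAULT_OUTLIER_CEILING = 5.0
PEAK_WINDOW_MINUTES = 24 * 60.0
STABILITY_FRACTION = 0.10
MIN_STABLE_MINUTES = 5.0

Segment = tuple[float, float, float]  # (start, end, rate), times in minutes


@dataclass
class DoseSummary:
    """Per-patient dose variables extracted from the infusion stream."""

    patient_id: object
    peak_dose_24h: float | None
    diagnosis_dose: float | None
    peak_ne_equivalent_24h: float | None
    no_stable_peak: bool = False
    outlier_excluded_records: int = 0


def weight_normalize(rate_ug_min: float, weight_kg: float) -> float:
    """Convert an absolute rate (ug/min) to a weight-normalised rate (ug/kg/min)."""
    if weight_kg is None or not math.isfinite(weight_kg) or weight_kg <= 0:
        raise ValueError(f"patient weight must be positive and known, got {weight_kg!r}")
    return float(rate_ug_min) / float(weight_kg)


def exclude_outlier_rates(
    segments: Sequence[Segment], max_rate: float = DEFAULT_OUTLIER_CEILING
) -> tuple[list[Segment], int]:
    """Drop records whose rate exceeds ``max_rate``; return (kept, n_excluded)."""
    if not (max_rate > 0):
        raise ValueError(f"outlier ceiling must be positive, got {max_rate!r}")
    kept = [s for s in segments if s[2] <= max_rate]
    return kept, len(segments) - len(kept)


def _validate_segments(segments: Sequence[Segment]) -> list[Segment]:
    segs = sorted((float(a), float(b), float(r)) for a, b, r in segments)
    prev_end = -math.inf
    for start, end, rate in segs:
        if not end > start:
            raise ValueError(f"segment end must exceed start: ({start}, {end})")
        if rate < 0 or not math.isfinite(rate):
            raise ValueError(f"segment rate must be finite and >= 0, got {rate}")
        if start < prev_end - 1e-9:
            raise ValueError(
                f"overlapping segments at t={start}; concurrent infusions are not supported"
            )
        prev_end = end
    return segs


def _clip(segments: Sequence[Segment], lo: float, hi: float) -> list[Segment]:
    out = []
    for start, end, rate in segments:
        s, e = max(start, lo), min(end, hi)
        if e > s:
            out.append((s, e, rate))
    return out


def _timeline_with_gaps(segments: list[Segment]) -> list[Segment]:
    """Insert explicit rate-0 segments into gaps so the step function is total."""
    out: list[Segment] = []
    for seg in segments:
        if out and seg[0] > out[-1][1] + 1e-9:
            out.append((out[-1][1], seg[0], 0.0))
        out.append(seg)
    return out


def stable_peak_dose(
    segments: Sequence[Segment],
    window_minutes: float = PEAK_WINDOW_MINUTES,
    stability: float = STABILITY_FRACTION,
    min_duration: float = MIN_STABLE_MINUTES,
) -> float | None:
    """Highest stable rate in ``[0, window_minutes]`` (times relative to diagnosis).

    Candidate rates are the distinct observed rates in descending order.  A
    candidate ``r`` qualifies if the piecewise-constant rate function stays
    inside the multiplicative band ``[r*(1-stability), r*(1+stability)]`` over
    a contiguous interval of length >= ``min_duration`` that contains at least
    one record at exactly ``r``.  Off-pump gaps count as rate 0 and break the
    band.  Returns None when no candidate qualifies (the patient is later
    excluded for having no valid dose values).
    """
    segs = _clip(_validate_segments(segments), 0.0, float(window_minutes))
    if not segs:
        return None
    timeline = _timeline_with_gaps(segs)
    for r in sorted({s[2] for s in segs}, reverse=True):
        lo, hi = r * (1.0 - stability), r * (1.0 + stability)
        run_len = 0.0
        run_has_r = False
        for start, end, rate in timeline:
            if lo - 1e-12 <= rate <= hi + 1e-12:
                run_len += end - start
                run_has_r = run_has_r or rate == r
                if run_has_r and run_len >= min_duration - 1e-9:
                    return r
            else:
                run_len, run_has_r = 0.0, False
    return None


def diagnosis_dose(segments: Sequence[Segment], t0: float = 0.0) -> float | None:
    """Rate of the record whose start time is nearest ``t0``; ties go earlier.

    This is the dose started or titrated closest to the shock diagnosis.
    """
    segs = _validate_segments(segments)
    if not segs:
        return None
    best = min(segs, key=lambda s: (abs(s[0] - t0), s[0]))
    return best[2]


def peak_ne_equivalent(
    segments_by_drug: Mapping[str, Sequence[Segment]],
    weights: NeEquivalentWeights | None = None,
    window_minutes: float = PEAK_WINDOW_MINUTES,
) -> float | None:
    """Maximum over time of the weighted multi-drug rate sum within the window.

    Each drug's rate must already be in its native unit (ug/kg/min for
    catecholamines, U/min for vasopressin).
    """
    w = weights or default_nee_weights()
    clipped = {
        drug: _clip(_validate_segments(segs), 0.0, float(window_minutes))
        for drug, segs in segments_by_drug.items()
    }
    breaks = sorted({t for segs in clipped.values() for s in segs for t in s[:2]})
    if len(breaks) < 2:
        return None
    best = None
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        total = 0.0
        for drug, segs in clipped.items():
            rate = next((r for s0, s1, r in segs if s0 <= mid < s1), 0.0)
            total += w.weight(drug) * rate
        best = total if best is None else max(best, total)
    return best


NE_DRUG = "norepinephrine"


def _segments_from_arrays(
    start: np.ndarray, end: np.ndarray, rate: np.ndarray, unit: np.ndarray,
    t0: pd.Timestamp, weight_kg: float | None,
) -> list[Segment]:
    """Event arrays -> (start, end, rate ug/kg/min) in minutes relative to t0."""
    t0_64 = np.datetime64(t0)
    minute = np.timedelta64(60, "s")
    s = (start - t0_64) / minute
    e = (end - t0_64) / minute
    segs = []
    for i in range(len(s)):
        u = unit[i]
        if u == "ug/kg/min" or u == "U/min":  # U/min: native unit, never normalised
            r = float(rate[i])
        elif u == "ug/min":
            r = weight_normalize(rate[i], weight_kg)
        else:
            raise ValueError(f"unrecognised rate unit {u!r}")
        segs.append((float(s[i]), float(e[i]), r))
    return segs


def _patient_segments(
    events: pd.DataFrame, t0: pd.Timestamp, weight_kg: float | None
) -> list[Segment]:
    """Event rows -> (start, end, rate ug/kg/min) in minutes relative to t0."""
    if not len(events):
        return []
    unit = (
        events["rate_unit"].to_numpy()
        if "rate_unit" in events.columns
        else np.full(len(events), "ug/kg/min")
    )
    return _segments_from_arrays(
        events["start_time"].to_numpy(), events["end_time"].to_numpy(),
        events["rate"].to_numpy(float), unit, t0, weight_kg,
    )


def summarize_patient(
    events: pd.DataFrame | None,
    patient_id: object,
    t0: pd.Timestamp,
    weight_kg: float | None = None,
    nee_weights: NeEquivalentWeights | None = None,
    outlier_ceiling: float = DEFAULT_OUTLIER_CEILING,
    window_minutes: float = PEAK_WINDOW_MINUTES,
) -> DoseSummary:
    """Dose variables for one patient's infusion events around shock time t0."""
    summary = DoseSummary(patient_id, None, None, None, no_stable_peak=True)
    if events is None or not len(events):
        return summary
    drug = events["drug"].to_numpy()
    start = events["start_time"].to_numpy()
    end = events["end_time"].to_numpy()
    rate = events["rate"].to_numpy(float)
    unit = (
        events["rate_unit"].to_numpy()
        if "rate_unit" in events.columns
        else np.full(len(events), "ug/kg/min")
    )
    is_ne = drug == NE_DRUG
    ne_segs = _segments_from_arrays(
        start[is_ne], end[is_ne], rate[is_ne], unit[is_ne], t0, weight_kg
    )
    ne_segs, n_out = exclude_outlier_rates(ne_segs, outlier_ceiling)
    summary.outlier_excluded_records = n_out
    if not ne_segs:
        return summary
    summary.diagnosis_dose = diagnosis_dose(ne_segs, 0.0)
    summary.peak_dose_24h = stable_peak_dose(ne_segs, window_minutes)
    summary.no_stable_peak = summary.peak_dose_24h is None
    all_segs = {NE_DRUG: ne_segs}
    for d in np.unique(drug[~is_ne]):
        m = drug == d
        all_segs[str(d)] = _segments_from_arrays(
            start[m], end[m], rate[m], unit[m], t0, weight_kg
        )
    summary.peak_ne_equivalent_24h = peak_ne_equivalent(all_segs, nee_weights, window_minutes)
    return summary


def dose_summaries(
    infusion_events: pd.DataFrame,
    shock_times: Mapping[object, pd.Timestamp],
    weights_kg: Mapping[object, float] | None = None,
    nee_weights: NeEquivalentWeights | None = None,
    outlier_ceiling: float = DEFAULT_OUTLIER_CEILING,
    window_minutes: float = PEAK_WINDOW_MINUTES,
) -> pd.DataFrame:
    """Extract :class:`DoseSummary` rows for every patient in ``shock_times``.

    ``infusion_events`` needs columns patient_id, drug, start_time, end_time,
    rate, rate_unit.  Only norepinephrine events enter the peak/diagnosis dose;
    all vasopressors enter the NE-equivalent peak.
    """
    weights_kg = weights_kg or {}
    by_patient = dict(tuple(infusion_events.groupby("patient_id", sort=False)))
    rows = [
        summarize_patient(
            by_patient.get(pid), pid, t0, weights_kg.get(pid),
            nee_weights, outlier_ceiling, window_minutes,
        ).__dict__
        for pid, t0 in shock_times.items()
    ]
    return pd.DataFrame(rows)
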