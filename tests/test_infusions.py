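"""Infusion stream processing: stability-filtered peak, diagnosis dose,
outlier removal, weight normalisation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from nedose.infusions import (
    diagnosis_dose,
    dose_summaries,
    exclude_outlier_rates,
    peak_ne_equivalent,
    stable_peak_dose,
    weight_normalize,
)


def brute_force_peak(segments, window=1440.0, stability=0.10, min_duration=5.0):
    """Independent oracle: exhaustive scan over all boundary-time intervals.

    For each distinct rate (descending) check every interval [a, b] between
    step-function boundaries for: length >= min_duration, all covered rates
    inside the band, and at least one covered record exactly at the rate.
    """
    segs = sorted((float(a), float(b), float(r)) for a, b, r in segments)
    clipped = [(max(s, 0.0), min(e, window), r) for s, e, r in segs if min(e, window) > max(s, 0.0)]
    if not clipped:
        return None
    timeline = []
    for s, e, r in clipped:
        if timeline and s > timeline[-1][1] + 1e-9:
            timeline.append((timeline[-1][1], s, 0.0))
        timeline.append((s, e, r))
    bounds = sorted({t for seg in timeline for t in seg[:2]})
    for r in sorted({r for *_, r in clipped}, reverse=True):
        lo, hi = r * (1 - stability), r * (1 + stability)
        for a, b in itertools.combinations(bounds, 2):
            if b - a < min_duration - 1e-9:
                continue
            cover = [seg for seg in timeline if seg[1] > a and seg[0] < b]
            if all(lo - 1e-12 <= seg[2] <= hi + 1e-12 for seg in cover) and any(
                seg[2] == r for seg in cover
            ):
                return r
    return None


class TestStablePeak:
    def test_single_long_segment_is_its_own_peak(self):
        assert stable_peak_dose([(0, 60, 0.30)]) == 0.30

    def test_short_excursion_rejected_second_highest_retrieved(self):
        # 2-minute excursion to 1.5 fails the 5-minute stability rule
        segs = [(0, 60, 0.30), (60, 62, 1.5), (62, 120, 0.30)]
        assert stable_peak_dose(segs) == 0.30

    def test_band_spans_adjacent_segments(self):
        # no single >=5-min segment at 0.50, but 0.48 stays within 10% of it,
        # giving 9 contiguous in-band minutes containing an exact 0.50 record
        segs = [(0, 3, 0.50), (3, 6, 0.48), (6, 9, 0.50)]
        assert stable_peak_dose(segs) == 0.50

    def test_gap_breaks_stability_interval(self):
        # two 3-min bursts at 0.4 separated by an off-pump gap never add up
        segs = [(0, 3, 0.4), (10, 13, 0.4), (20, 120, 0.2)]
        assert stable_peak_dose(segs) == 0.2

    def test_no_qualifying_rate_returns_missing(self):
        assert stable_peak_dose([(0, 2, 0.5), (10, 12, 0.3)]) is None
        assert stable_peak_dose([]) is None

    def test_events_outside_window_ignored(self):
        segs = [(0, 60, 0.2), (1500, 1700, 0.9)]
        assert stable_peak_dose(segs) == 0.2

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            stable_peak_dose([(0, 10, 0.2), (5, 15, 0.3)])

    def test_split_invariance(self):
        """Splitting any segment into identical-rate sub-segments changes nothing."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(1, 6)
            t, segs = 0.0, []
            for _ in range(n):
                dur = float(rng.uniform(1, 40))
                segs.append((t, t + dur, float(rng.choice([0.1, 0.3, 0.32, 0.5]))))
                t += dur
            split = []
            for s, e, r in segs:
                mid = (s + e) / 2
                split += [(s, mid, r), (mid, e, r)]
            assert stable_peak_dose(split) == stable_peak_dose(segs)

    def test_peak_bounded_by_observed_maximum(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t, segs = 0.0, []
            for _ in range(rng.integers(1, 8)):
                dur = float(rng.uniform(0.5, 30))
                segs.append((t, t + dur, round(float(rng.uniform(0, 1)), 2)))
                t += dur
            peak = stable_peak_dose(segs)
            if peak is not None:
                assert peak <= max(r for *_, r in segs)

    def test_matches_brute_force_on_random_streams(self):
        """Exhaustive-interval oracle agreement on randomized <=10-event streams."""
        rng = np.random.default_rng(2024)
        rates = [0.1, 0.2, 0.22, 0.3, 0.33, 0.5, 0.55, 1.0]
        for _ in range(300):
            t, segs = float(rng.uniform(0, 5)), []
            for _ in range(rng.integers(1, 11)):
                if rng.random() < 0.2:  # off-pump gap
                    t += float(rng.uniform(1, 20))
                dur = float(rng.uniform(0.5, 25))
                segs.append((t, t + dur, float(rng.choice(rates))))
                t += dur
            assert stable_peak_dose(segs) == brute_force_peak(segs)


class TestDiagnosisDose:
    def test_nearest_start_before_wins(self):
        assert diagnosis_dose([(-10, -5, 0.05), (30, 60, 0.2)], 0.0) == 0.05

    def test_single_event_at_t0(self):
        assert diagnosis_dose([(0, 30, 0.1)], 0.0) == 0.1

    def test_tie_broken_toward_earlier_event(self):
        assert diagnosis_dose([(-5, -1, 0.08), (5, 30, 0.12)], 0.0) == 0.08

    def test_empty_stream_missing(self):
        assert diagnosis_dose([], 0.0) is None


class TestOutlierFilter:
    def test_removes_rates_above_ceiling(self):
        kept, n = exclude_outlier_rates([(0, 5, 0.2), (5, 10, 0.4), (10, 11, 7.0)], 5.0)
        assert [r for *_, r in kept] == [0.2, 0.4] and n == 1

    def test_untouched_when_all_below(self):
        kept, n = exclude_outlier_rates([(0, 5, 0.2)], 5.0)
        assert kept == [(0, 5, 0.2)] and n == 0

    def test_all_outliers_leaves_empty_stream(self):
        kept, n = exclude_outlier_rates([(0, 5, 9.0), (5, 9, 12.0)], 5.0)
        assert kept == [] and n == 2


class TestWeightNormalize:
    @pytest.mark.parametrize(
        "rate,kg,expected", [(16, 80, 0.2), (0, 70, 0.0), (24, 79, 24 / 79)]
    )
    def test_arithmetic(self, rate, kg, expected):
        assert weight_normalize(rate, kg) == pytest.approx(expected)

    def test_missing_weight_is_an_error(self):
        for bad in (None, float("nan"), 0.0, -5.0):
            with pytest.raises(ValueError, match="weight"):
                weight_normalize(10.0, bad)


class TestNeEquivalentPeak:
    def test_concurrent_drugs_summed_with_weights(self):
        segs = {
            "norepinephrine": [(0, 60, 0.2)],
            "vasopressin": [(30, 90, 0.04)],  # weight 2.5 per U/min
        }
        # [30, 60): 0.2 + 0.1 = 0.3 is the maximum
        assert peak_ne_equivalent(segs) == pytest.approx(0.3)

    def test_ne_alone_reduces_to_ne_peak_rate(self):
        assert peak_ne_equivalent({"norepinephrine": [(0, 30, 0.25)]}) == pytest.approx(0.25)


class TestDoseSummaries:
    def test_frame_level_extraction(self):
        t0 = pd.Timestamp("2023-01-01 12:00")
        ev = pd.DataFrame(
            {
                "patient_id": [1, 1, 1],
                "drug": ["norepinephrine"] * 3,
                "start_time": [t0, t0 + pd.Timedelta(minutes=60), t0 + pd.Timedelta(minutes=120)],
                "end_time": [
                    t0 + pd.Timedelta(minutes=60),
                    t0 + pd.Timedelta(minutes=120),
                    t0 + pd.Timedelta(minutes=121),
                ],
                "rate": [0.1, 0.3, 8.0],
                "rate_unit": ["ug/kg/min"] * 3,
            }
        )
        out = dose_summaries(ev, {1: t0}, {1: 80.0})
        row = out.iloc[0]
        assert row["diagnosis_dose"] == 0.1
        assert row["peak_dose_24h"] == 0.3
        assert row["outlier_excluded_records"] == 1
        assert not row["no_stable_peak"]

    def test_absolute_rates_normalised_by_weight(self):
        t0 = pd.Timestamp("2023-01-01 12:00")
        ev = pd.DataFrame(
            {
                "patient_id": [1],
                "drug": ["norepinephrine"],
                "start_time": [t0],
                "end_time": [t0 + pd.Timedelta(minutes=30)],
                "rate": [16.0],
                "rate_unit": ["ug/min"],
            }
        )
        out = dose_summaries(ev, {1: t0}, {1: 80.0})
        assert out.iloc[0]["peak_dose_24h"] == pytest.approx(0.2)
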