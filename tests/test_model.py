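"""Dose-response modelling: stacking, fit variants, the rescaling identity,
odds-ratio arithmetic, and threshold predictions."""

import math

import numpy as np
import pandas as pd
import pytest

from nedose.formulations import default_formulations
from nedose.model import (
    FitError,
    expected_slope,
    fit_dose_response,
    fit_from_anchors,
    percent_or_reduction,
    predict_mortality,
    round_half_up_percent,
    stack_formulations,
    threshold_table,
)
from nedose.simulate import (
    DIAGNOSIS_DOSE_ANCHORS,
    calibrate_logistic_from_anchors,
    simulate_dose_mortality,
)

REG = default_formulations()


def _cohort_from_sim(n, alpha, beta, seed):
    df = simulate_dose_mortality(n, alpha, beta, 0.1, 0.05, 0.2, np.random.default_rng(seed))
    return pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "diagnosis_dose": df["dose"],
            "death_28d": df["death"],
        }
    )


@pytest.fixture(scope="module")
def sim_design():
    a, b = calibrate_logistic_from_anchors(DIAGNOSIS_DOSE_ANCHORS)
    cohort = _cohort_from_sim(6000, a, b, 31)
    return stack_formulations(cohort, "diagnosis_dose")


class TestStacking:
    def test_published_median_converts_to_all_formulations(self):
        cohort = pd.DataFrame({"patient_id": [1], "diagnosis_dose": [0.24], "death_28d": [0]})
        d = stack_formulations(cohort)
        assert sorted(d["dose"].round(4)) == [0.24, 0.2928, 0.4536, 0.48]

    def test_empty_cohort_gives_empty_design(self):
        d = stack_formulations(
            pd.DataFrame({"patient_id": [], "diagnosis_dose": [], "death_28d": []})
        )
        assert len(d) == 0

    def test_four_rows_per_patient(self):
        cohort = pd.DataFrame(
            {"patient_id": range(7), "diagnosis_dose": np.linspace(0.05, 1, 7),
             "death_28d": [0, 1] * 3 + [0]}
        )
        d = stack_formulations(cohort)
        assert len(d) == 28
        # within a patient the base dose is identical across rows
        for _, g in d.groupby("patient_id"):
            base = {row.dose / REG[row.formulation].factor for row in g.itertuples()}
            assert max(base) - min(base) < 1e-12

    def test_missing_dose_column_is_an_error(self):
        with pytest.raises(KeyError):
            stack_formulations(pd.DataFrame({"patient_id": [1], "death_28d": [1]}), "peak_dose_24h")


class TestFitVariants:
    def test_rescaling_oracle_on_fitted_cohort(self, sim_design):
        """beta_f * c_f == beta_base: the salt fits are exact reparameterisations."""
        fit = fit_dose_response(sim_design, "per_formulation")
        base = fit.fits["base"]
        for name, ff in fit.fits.items():
            c = REG[name].factor
            assert ff.beta * c == pytest.approx(base.beta, abs=1e-8)
            assert ff.alpha == pytest.approx(base.alpha, abs=1e-8)

    def test_interaction_and_separate_fits_agree(self, sim_design):
        sep = fit_dose_response(sim_design, "per_formulation")
        inter = fit_dose_response(sim_design, "interaction")
        for name in REG:
            assert inter.fits[name].beta == pytest.approx(sep.fits[name].beta, abs=1e-6)
            assert inter.fits[name].alpha == pytest.approx(sep.fits[name].alpha, abs=1e-6)

    def test_null_generator_recovers_unit_odds_ratio(self):
        cohort = _cohort_from_sim(4000, 0.0, 0.0, 5)
        fit = fit_dose_response(stack_formulations(cohort, "diagnosis_dose"))
        for ff in fit.fits.values():
            lo, hi = ff.odds_ratio_ci()
            assert lo < 1.0 < hi

    def test_random_intercept_variant_reports_variance_component(self):
        a, b = calibrate_logistic_from_anchors(DIAGNOSIS_DOSE_ANCHORS)
        design = stack_formulations(_cohort_from_sim(300, a, b, 8), "diagnosis_dose")
        fit = fit_dose_response(design, "interaction_random_intercept")
        # the stacked rows are deterministic copies of one observation, so the
        # variance component is weakly identified: it is reported, never
        # interpreted, and the coefficients are not expected to match the
        # maximum-likelihood fits
        assert fit.random_intercept_sd is not None and fit.random_intercept_sd >= 0
        assert all(np.isfinite([ff.alpha, ff.beta]).all() for ff in fit.fits.values())

    def test_degenerate_outcome_raises_fit_error(self):
        cohort = pd.DataFrame(
            {"patient_id": range(10), "diagnosis_dose": np.linspace(0.1, 1, 10),
             "death_28d": np.zeros(10, dtype=int)}
        )
        with pytest.raises(FitError):
            fit_dose_response(stack_formulations(cohort, "diagnosis_dose"))

    def test_unknown_variant_rejected(self, sim_design):
        with pytest.raises(ValueError):
            fit_dose_response(sim_design, "spline")


class TestRescalingArithmetic:
    def test_expected_slope_base_is_identity(self):
        assert expected_slope(1.7, "base") == 1.7

    def test_tartrate_or_reduction_matches_published_67(self):
        or_t = math.exp(expected_slope(math.log(9.4), "tartrate"))
        assert or_t == pytest.approx(3.066, abs=1e-3)
        assert percent_or_reduction(or_t, 9.4) == pytest.approx(67.4, abs=0.05)

    def test_bitartrate_or_reduction_matches_published_65(self):
        or_b = math.exp(expected_slope(math.log(9.4), "bitartrate"))
        assert percent_or_reduction(or_b, 9.4) == pytest.approx(65.2, abs=0.05)

    def test_hydrochloride_or_reduction_matches_published_33(self):
        or_h = math.exp(expected_slope(math.log(9.4), "hydrochloride"))
        assert or_h == pytest.approx(9.4 ** (1 / 1.22), abs=1e-9)
        assert percent_or_reduction(or_h, 9.4) == pytest.approx(33.2, abs=0.05)

    def test_equal_ors_give_zero_reduction(self):
        assert percent_or_reduction(2.5, 2.5) == 0.0

    def test_nonpositive_or_rejected(self):
        with pytest.raises(ValueError):
            percent_or_reduction(-1.0, 9.4)


@pytest.fixture(scope="module")
def anchored():
    return fit_from_anchors(DIAGNOSIS_DOSE_ANCHORS)


class TestPrediction:

    def test_base_cell_at_one(self, anchored):
        p, _ = predict_mortality(anchored, 1.0, "base")
        assert p == pytest.approx(0.810, abs=5e-4)

    def test_tartrate_reported_one_equals_base_half(self, anchored):
        p, _ = predict_mortality(anchored, 1.0, "tartrate")
        assert p == pytest.approx(0.580, abs=5e-4)

    def test_dose_zero_is_logistic_of_intercept(self, anchored):
        from scipy.special import expit

        p, _ = predict_mortality(anchored, 0.0, "tartrate")
        assert p == pytest.approx(float(expit(anchored.fits["tartrate"].alpha)))

    def test_prediction_equivariance(self, sim_design):
        """predict(f, d) == predict(base, d/c_f) for every formulation."""
        fit = fit_dose_response(sim_design)
        for name in REG:
            c = REG[name].factor
            for d in (0.0, 0.1, 0.25, 0.5, 1.0):
                pf, _ = predict_mortality(fit, d, name)
                pb, _ = predict_mortality(fit, d / c, "base")
                assert pf == pytest.approx(pb, abs=1e-8)

    def test_ci_contains_point_and_stays_in_unit_interval(self, sim_design):
        fit = fit_dose_response(sim_design)
        for d in (0.05, 0.3, 1.0, 2.0):
            p, (lo, hi) = predict_mortality(fit, d, "base")
            assert 0.0 <= lo <= p <= hi <= 1.0
            assert hi - lo > 0

    def test_negative_dose_rejected(self, anchored):
        with pytest.raises(ValueError):
            predict_mortality(anchored, -0.1, "base")

    def test_divergence_grows_with_dose(self, anchored):
        """Base-vs-tartrate predicted-mortality gap widens monotonically over
        the clinically observed range."""
        doses = np.linspace(0.01, 1.0, 50)
        gaps = []
        for d in doses:
            pb, _ = predict_mortality(anchored, d, "base")
            pt, _ = predict_mortality(anchored, d, "tartrate")
            if pb <= 0.85:
                gaps.append(pb - pt)
        assert all(g2 > g1 for g1, g2 in zip(gaps, gaps[1:]))


class TestThresholdTable:
    def test_tartrate_diagnosis_column_matches_published(self):
        tt = threshold_table(fit_from_anchors(DIAGNOSIS_DOSE_ANCHORS))
        col = tt[tt.formulation == "tartrate"].sort_values("threshold")["percent"]
        assert list(col) == [33, 37, 58]

    def test_base_column_at_quarter_threshold(self):
        tt = threshold_table(fit_from_anchors(DIAGNOSIS_DOSE_ANCHORS))
        cell = tt[(tt.formulation == "base") & (tt.threshold == 0.25)]["percent"].item()
        assert cell == 44

    def test_flat_fit_has_identical_cells(self):
        tt = threshold_table(fit_from_anchors([(0.0, 0.5), (1.0, 0.5)]))
        assert tt["percent"].nunique() == 1

    def test_ci_columns_bracket_estimate(self, sim_design):
        tt = threshold_table(fit_dose_response(sim_design))
        assert ((tt.ci_low <= tt.p_death) & (tt.p_death <= tt.ci_high)).all()

    def test_half_up_rounding(self):
        assert round_half_up_percent(0.435) == 44
        assert round_half_up_percent(0.4449) == 44
        assert round_half_up_percent(0.445) == 45


class TestParameterRecovery:
    def test_mean_or_within_monte_carlo_error(self):
        """200 simulated cohorts at the study's size: mean estimated OR within
        2 MC standard errors of the generating OR."""
        a, b = calibrate_logistic_from_anchors(DIAGNOSIS_DOSE_ANCHORS)
        ors = []
        for r in range(200):
            design = _cohort_from_sim(4086, a, b, 50_000 + r)
            fit = fit_dose_response(stack_formulations(design, "diagnosis_dose"))
            ors.append(fit.fits["base"].odds_ratio)
        mc_se = np.std(ors, ddof=1) / math.sqrt(len(ors))
        assert abs(np.mean(ors) - math.exp(b)) < 2 * mc_se
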