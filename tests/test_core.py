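"""Unit and property tests for the pairing model and rate estimators."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from n2pair import (
    IncubationDesign,
    IsotopologueSeries,
    LabeledFraction,
    ProductionRates,
    Treatment,
    compute_labeled_fraction,
    contribution_and_total,
    estimate_rate_ammonium_label,
    estimate_rates_nitrite_label,
    fit_production_rates,
    forward_pairing,
    headspace_to_aqueous,
)
from n2pair.core import InsufficientDataError, NonIdentifiableError

fractions = st.floats(min_value=0.0, max_value=1.0)
rates = st.floats(min_value=0.0, max_value=100.0)


def make_production(p29=0.0, p30=0.0, se29=0.0, se30=0.0, pv29=1.0, pv30=1.0):
    return ProductionRates(
        p29=p29, p30=p30, se_p29=se29, se_p30=se30,
        r2_29=1.0, r2_30=1.0, p_value_29=pv29, p_value_30=pv30, n_points=15,
    )


class TestLabeledFraction:
    @pytest.mark.parametrize(
        "added, background, expected",
        [
            (5.0, 0.0, 1.0),  # no dilution
            (50.0, 30.0, 0.625),  # ammonium spike into a 30 uM background
            (0.0, 5.0, 0.0),  # unlabeled pool
            (5.0, 5.0, 0.5),
        ],
    )
    def test_background_convention(self, added, background, expected):
        assert compute_labeled_fraction(added, background_14n=background) == pytest.approx(expected)

    def test_measured_total_convention(self):
        # ammonium convention: total assayed after the spike
        assert compute_labeled_fraction(50.0, measured_total=80.0) == pytest.approx(0.625)

    def test_exactly_one_total_source_required(self):
        with pytest.raises(ValueError):
            compute_labeled_fraction(5.0)
        with pytest.raises(ValueError):
            compute_labeled_fraction(5.0, background_14n=1.0, measured_total=6.0)

    def test_inconsistent_measured_total_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            compute_labeled_fraction(50.0, measured_total=40.0)

    def test_zero_total_with_label_rejected(self):
        with pytest.raises(ValueError):
            compute_labeled_fraction(5.0, measured_total=0.0)

    @given(added=st.floats(0.0, 1e3), background=st.floats(0.0, 1e3))
    def test_fraction_always_in_unit_interval(self, added, background):
        f = compute_labeled_fraction(added, background_14n=background)
        assert 0.0 <= f <= 1.0


class TestForwardPairing:
    def test_anammox_with_fully_labeled_ammonium_makes_only_29(self):
        p = forward_pairing(1.0, 0.0, LabeledFraction(f_nitrite=0.0, f_ammonium=1.0))
        assert (p.p28, p.p29, p.p30) == (0.0, 1.0, 0.0)

    def test_denitrification_fully_labeled_nitrite_makes_only_30(self):
        p = forward_pairing(0.0, 1.0, LabeledFraction(f_nitrite=1.0))
        assert (p.p28, p.p29, p.p30) == (0.0, 0.0, 1.0)

    @given(a=rates, d=rates, fn=fractions, fa=fractions)
    def test_conservation(self, a, d, fn, fa):
        """Isotopologue rates always sum to the total N2 production A + D."""
        p = forward_pairing(a, d, LabeledFraction(f_nitrite=fn, f_ammonium=fa))
        assert p.total == pytest.approx(a + d, rel=1e-12, abs=1e-12)
        assert min(p.p28, p.p29, p.p30) >= 0.0

    @given(fn=st.floats(0.01, 0.99))
    def test_classic_ipt_ratio_without_anammox(self, fn):
        """Pure denitrification: P29/P30 = 2(1-Fn)/Fn, the classic pairing ratio."""
        p = forward_pairing(0.0, 5.0, LabeledFraction(f_nitrite=fn))
        assert p.p29 / p.p30 == pytest.approx(2.0 * (1.0 - fn) / fn, rel=1e-12)

    def test_p30_strictly_increasing_in_label_fraction(self):
        fns = np.linspace(0.05, 1.0, 20)
        p30 = [forward_pairing(0.0, 2.0, LabeledFraction(f_nitrite=f)).p30 for f in fns]
        assert np.all(np.diff(p30) > 0)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            forward_pairing(-1.0, 0.0, LabeledFraction(f_nitrite=1.0))


class TestHeadspacePartition:
    def test_headspace_only_normalization(self, default_design):
        assert headspace_to_aqueous(0.105, default_design) == pytest.approx(3.5)

    def test_zero_amount(self, default_design):
        assert headspace_to_aqueous(0.0, default_design) == 0.0

    @given(amount=st.floats(0.0, 10.0))
    def test_zero_solubility_matches_headspace_only(self, amount):
        design = IncubationDesign()
        off = headspace_to_aqueous(amount, design, include_dissolved=False)
        on = headspace_to_aqueous(
            amount, design, include_dissolved=True, solubility_coeff=0.0
        )
        assert on == pytest.approx(off)

    def test_dissolved_correction_increases_amount(self, default_design):
        base = headspace_to_aqueous(1.0, default_design)
        corrected = headspace_to_aqueous(
            1.0, default_design, include_dissolved=True, solubility_coeff=0.015
        )
        assert corrected == pytest.approx(base * (1 + 0.015 * 30.0 / 8.0))


class TestFitProductionRates:
    def test_exact_line_recovered(self):
        t = np.array([0.0, 14.0, 24.0, 36.0, 48.0])
        df = pd.DataFrame(
            {
                "time_h": t,
                "replicate": [f"R{i}" for i in range(len(t))],
                "excess29_nmol_per_L": 2.0 * t / 24.0,
                "excess30_nmol_per_L": 0.0,
            }
        )
        fit = fit_production_rates(IsotopologueSeries(df))
        assert fit.p29 == pytest.approx(2.0, abs=1e-10)
        assert fit.se_p29 == pytest.approx(0.0, abs=1e-8)
        assert fit.r2_29 == pytest.approx(1.0)
        assert fit.p_value_29 < 1e-6

    def test_three_point_hand_ols(self):
        # x (d) = (0, 1, 2), y = (0, 1.0, 2.4): slope = cov/var = 2.4/2 = 1.2
        df = pd.DataFrame(
            {
                "time_h": [0.0, 24.0, 48.0],
                "replicate": ["a", "b", "c"],
                "excess29_nmol_per_L": [0.0, 1.0, 2.4],
                "excess30_nmol_per_L": [0.0, 0.0, 0.0],
            }
        )
        fit = fit_production_rates(IsotopologueSeries(df))
        assert fit.p29 == pytest.approx(1.2, rel=1e-12)

    def test_null_signal_is_not_detected(self):
        df = pd.DataFrame(
            {
                "time_h": [0.0, 24.0, 48.0] * 3,
                "replicate": list("abcdefghi"),
                "excess29_nmol_per_L": 0.0,
                "excess30_nmol_per_L": 0.0,
            }
        )
        fit = fit_production_rates(IsotopologueSeries(df))
        assert fit.p29 == 0.0
        assert fit.p_value_29 >= 0.5

    def test_insufficient_distinct_times_rejected(self):
        df = pd.DataFrame(
            {
                "time_h": [0.0, 0.0, 24.0],
                "replicate": list("abc"),
                "excess29_nmol_per_L": [0.0, 0.1, 1.0],
                "excess30_nmol_per_L": 0.0,
            }
        )
        with pytest.raises(InsufficientDataError):
            fit_production_rates(IsotopologueSeries(df))

    def test_degenerate_single_time_rejected(self):
        df = pd.DataFrame(
            {
                "time_h": [24.0] * 3,
                "replicate": list("abc"),
                "excess29_nmol_per_L": [1.0, 1.1, 0.9],
                "excess30_nmol_per_L": 0.0,
            }
        )
        with pytest.raises(InsufficientDataError):
            fit_production_rates(IsotopologueSeries(df))

    def test_replicate_averaging_option(self, noiseless_series):
        pooled = fit_production_rates(noiseless_series)
        averaged = fit_production_rates(noiseless_series, average_replicates=True)
        assert averaged.p29 == pytest.approx(pooled.p29, rel=1e-12)
        assert averaged.n_points == 5


class TestNitriteLabelEstimator:
    def test_undiluted_label_gives_headline_partition(self):
        """With Fn = 1 the slopes are the rates: A = P29, D = P30."""
        proc = estimate_rates_nitrite_label(
            make_production(p29=3.5, p30=0.7, pv29=0.001, pv30=0.01),
            LabeledFraction(f_nitrite=1.0),
        )
        assert proc.anammox == pytest.approx(3.5)
        assert proc.denitrification == pytest.approx(0.7)
        assert proc.total == pytest.approx(4.2)
        assert proc.contribution == pytest.approx(5.0 / 6.0)
        assert proc.detected_a and proc.detected_d

    def test_forward_inverse_round_trip_pure_denitrification(self):
        proc = estimate_rates_nitrite_label(
            make_production(p29=2.0, p30=1.0, pv29=0.001, pv30=0.001),
            LabeledFraction(f_nitrite=0.5),
        )
        assert proc.anammox == pytest.approx(0.0, abs=1e-12)
        assert proc.denitrification == pytest.approx(4.0)

    @given(a=rates, d=rates, fn=st.floats(0.05, 1.0))
    def test_forward_inverse_round_trip(self, a, d, fn):
        """Inverting the pairing model recovers the rates that generated it."""
        f = LabeledFraction(f_nitrite=fn, f_ammonium=0.0)
        p = forward_pairing(a, d, f)
        proc = estimate_rates_nitrite_label(
            make_production(p29=p.p29, p30=p.p30, pv29=0.0, pv30=0.0), f
        )
        assert proc.anammox == pytest.approx(a, rel=1e-9, abs=1e-9)
        assert proc.denitrification == pytest.approx(d, rel=1e-9, abs=1e-9)

    def test_zero_slopes_give_zero_undetected_rates(self):
        proc = estimate_rates_nitrite_label(
            make_production(), LabeledFraction(f_nitrite=1.0)
        )
        assert proc.anammox == 0.0 and proc.denitrification == 0.0
        assert not proc.detected_a and not proc.detected_d

    def test_unlabeled_nitrite_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            estimate_rates_nitrite_label(
                make_production(p29=1.0), LabeledFraction(f_nitrite=0.0)
            )

    def test_negative_anammox_reported_with_warning_not_clamped(self):
        # 29N2 slope below the denitrification-only expectation at Fn=0.5
        with pytest.warns(UserWarning, match="negative anammox"):
            proc = estimate_rates_nitrite_label(
                make_production(p29=0.1, p30=1.0, pv29=0.001, pv30=0.001),
                LabeledFraction(f_nitrite=0.5),
            )
        assert proc.anammox < 0
        assert not proc.detected_a
        assert proc.warnings_

    def test_bootstrap_agrees_with_delta_method(self):
        """Bottle-resampling bootstrap SEs land near the delta-method SEs."""
        from n2pair import (
            SimulationSpec,
            bootstrap_rates_nitrite_label,
            simulate_incubation,
        )

        f = LabeledFraction(f_nitrite=1.0)
        series = simulate_incubation(
            SimulationSpec(noise_sd=0.5, f=f, seed=4)
        )
        proc = estimate_rates_nitrite_label(fit_production_rates(series), f)
        boot = bootstrap_rates_nitrite_label(series, f, n_boot=400, seed=1)
        assert boot["anammox"].std() == pytest.approx(proc.se_a, rel=0.5)
        assert boot["denitrification"].std() == pytest.approx(proc.se_d, rel=0.5)
        again = bootstrap_rates_nitrite_label(series, f, n_boot=400, seed=1)
        pd.testing.assert_frame_equal(boot, again)

    def test_delta_method_standard_errors(self):
        fn = 0.5
        proc = estimate_rates_nitrite_label(
            make_production(p29=2.0, p30=1.0, se29=0.2, se30=0.1),
            LabeledFraction(f_nitrite=fn),
        )
        assert proc.se_d == pytest.approx(0.1 / fn**2)
        expected_se_a = math.hypot(0.2 / fn, 2 * (1 - fn) / fn**2 * 0.1)
        assert proc.se_a == pytest.approx(expected_se_a)


class TestAmmoniumLabelEstimator:
    @pytest.mark.parametrize(
        "fa, p29, expected", [(1.0, 4.7, 4.7), (0.625, 2.5, 4.0), (1.0, 0.0, 0.0)]
    )
    def test_anammox_rate(self, fa, p29, expected):
        proc = estimate_rate_ammonium_label(
            make_production(p29=p29, pv29=0.001),
            LabeledFraction(f_nitrite=0.0, f_ammonium=fa),
        )
        assert proc.anammox == pytest.approx(expected)
        assert math.isnan(proc.denitrification)
        assert not proc.detected_d

    def test_significant_30n2_flags_model_violation(self):
        with pytest.warns(UserWarning, match="30N2"):
            proc = estimate_rate_ammonium_label(
                make_production(p29=1.0, p30=0.5, pv29=0.001, pv30=0.001),
                LabeledFraction(f_nitrite=0.0, f_ammonium=1.0),
            )
        assert any("30N2" in w for w in proc.warnings_)

    def test_unlabeled_ammonium_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            estimate_rate_ammonium_label(
                make_production(p29=1.0), LabeledFraction(f_nitrite=0.0, f_ammonium=0.0)
            )


class TestContributionAndTotal:
    def test_headline_worked_example(self):
        total, contribution, flag = contribution_and_total(3.5, 0.7)
        assert total == pytest.approx(4.2)
        assert round(contribution * 100) == 83
        assert flag is None

    @pytest.mark.parametrize("a, d, expected", [(0.0, 5.0, 0.0), (5.0, 0.0, 1.0)])
    def test_pure_process_limits(self, a, d, expected):
        total, contribution, _ = contribution_and_total(a, d)
        assert total == pytest.approx(a + d)
        assert contribution == expected

    def test_zero_total_is_flagged_undefined(self):
        total, contribution, flag = contribution_and_total(0.0, 0.0)
        assert total == 0.0
        assert math.isnan(contribution)
        assert "undefined" in flag

    def test_negative_rate_raw_vs_clamped(self):
        _, raw, flag_raw = contribution_and_total(-0.5, 1.0)
        assert raw < 0 and "raw" in flag_raw
        _, clamped, flag_clamp = contribution_and_total(
            -0.5, 1.0, clamp_contribution=True
        )
        assert clamped == 0.0 and "clamped" in flag_clamp


class TestDesignValidation:
    def test_default_design_is_valid(self, default_design):
        assert default_design.sampling_times_h == (0.0, 14.0, 24.0, 36.0, 48.0)
        assert default_design.labeled_fractions().f_nitrite == 1.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"water_volume_ml": 0.0},
            {"sampling_times_h": (14.0, 24.0)},  # no t = 0
            {"sampling_times_h": (0.0, 24.0, 24.0)},  # not strictly increasing
            {"replicates_per_time": 0},
            {"background_nitrite": -1.0},
            {"treatment": Treatment.NITRITE_15N, "added_15n_ammonium": 5.0},
            {"treatment": Treatment.AMMONIUM_15N, "added_15n_nitrite": 5.0},
        ],
    )
    def test_invalid_designs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            IncubationDesign(**kwargs)

    def test_background_dilutes_label(self):
        design = IncubationDesign(added_15n_nitrite=5.0, background_nitrite=5.0)
        assert design.labeled_fractions().f_nitrite == pytest.approx(0.5)

    def test_series_times_must_match_schedule(self, default_design):
        df = pd.DataFrame(
            {
                "time_h": [0.0, 11.0],
                "replicate": ["a", "b"],
                "excess29_nmol_per_L": [0.0, 1.0],
                "excess30_nmol_per_L": [0.0, 0.0],
            }
        )
        with pytest.raises(ValueError, match="not in design schedule"):
            IsotopologueSeries(df, design=default_design)

    def test_negative_excess_flagged_not_rejected(self, default_design):
        df = pd.DataFrame(
            {
                "time_h": [0.0, 14.0, 24.0],
                "replicate": ["a", "b", "c"],
                "excess29_nmol_per_L": [-0.05, 0.5, 1.0],
                "excess30_nmol_per_L": [0.0, 0.0, 0.0],
            }
        )
        series = IsotopologueSeries(df, design=default_design)
        assert len(series.negative_flags) == 1
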