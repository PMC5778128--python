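"""Open-system isotope mass balance and the scenario registry."""

import pytest
from hypothesis import given, settings, strategies as st

from permaom import (
    FractionationScenario,
    IsotopeShift,
    ParameterError,
    UndefinedModelError,
    default_scenarios,
    evaluate_scenarios,
    forward_delta,
    fraction_oxidized,
    retained_bounds,
)
from permaom.fractionation import scenarios_from_yaml, scenarios_to_yaml


def shift_of(delta_o, delta_p):
    return IsotopeShift(delta_o=delta_o, delta_p=delta_p, depth_o=10.0, depth_p=20.0)


SHIFT_35 = shift_of(-37.0, -72.0)


class TestFractionOxidized:
    def test_marine_high_hand_value(self):
        sc = FractionationScenario("x", 1.039, 1.001)
        assert fraction_oxidized(SHIFT_35, sc) == pytest.approx(35.0 / 38.0, rel=1e-12)

    def test_marine_low_exceeds_one(self):
        sc = FractionationScenario("x", 1.009, 1.001)
        assert fraction_oxidized(SHIFT_35, sc) == pytest.approx(35.0 / 8.0, rel=1e-12)

    def test_zero_shift_gives_zero_for_every_scenario(self):
        zero = shift_of(-50.0, -50.0)
        assert all(fraction_oxidized(zero, sc) == 0.0 for sc in default_scenarios())

    def test_equal_alphas_raise_undefined_model(self):
        sc = FractionationScenario("degenerate", 1.001, 1.001)
        with pytest.raises(UndefinedModelError):
            fraction_oxidized(SHIFT_35, sc)

    @given(
        delta_p=st.floats(-90.0, -52.001),
        shift=st.floats(0.1, 40.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_shift(self, delta_p, shift):
        sc = FractionationScenario("x", 1.030, 1.001)
        f1 = fraction_oxidized(shift_of(delta_p + shift, delta_p), sc)
        f2 = fraction_oxidized(shift_of(delta_p + 2.0 * shift, delta_p), sc)
        assert f2 == pytest.approx(2.0 * f1, rel=1e-9)

    def test_strictly_decreasing_in_alpha_ox_for_positive_shift(self):
        alphas = [1.009, 1.0174, 1.030, 1.031, 1.032, 1.039]
        fs = [
            fraction_oxidized(SHIFT_35, FractionationScenario("x", a, 1.001))
            for a in alphas
        ]
        assert all(a > b for a, b in zip(fs, fs[1:]))


class TestForwardInverse:
    def test_hand_value_inverse_of_marine_high(self):
        sc = FractionationScenario("x", 1.039, 1.001)
        assert forward_delta(0.9210526315789465, -72.0, sc) == pytest.approx(
            -37.0, abs=1e-9
        )

    def test_zero_fraction_returns_source_signature(self):
        sc = default_scenarios()[0]
        assert forward_delta(0.0, -63.0, sc) == -63.0

    @given(
        f=st.floats(0.0, 1.0),
        delta_p=st.floats(-90.0, -52.0),
        idx=st.integers(0, 5),
    )
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_to_1e12(self, f, delta_p, idx):
        sc = default_scenarios()[idx]
        delta_o = forward_delta(f, delta_p, sc)
        shift = IsotopeShift(delta_o, delta_p, depth_o=1.0, depth_p=2.0)
        assert fraction_oxidized(shift, sc) == pytest.approx(f, abs=1e-12)


class TestRegistry:
    def test_exactly_six_printed_alpha_values(self):
        scs = default_scenarios()
        assert sorted(sc.alpha_ox for sc in scs) == [
            1.009, 1.0174, 1.030, 1.031, 1.032, 1.039,
        ]

    def test_all_share_soil_transport_factor(self):
        assert all(sc.alpha_trans == 1.001 for sc in default_scenarios())

    def test_marine_bounds_present(self):
        by_name = {sc.name: sc.alpha_ox for sc in default_scenarios()}
        assert by_name["S-AOM-marine-low"] == 1.009
        assert by_name["S-AOM-marine-high"] == 1.039

    def test_pure_function(self):
        assert default_scenarios() == default_scenarios()

    def test_yaml_round_trip(self, tmp_path):
        path = scenarios_to_yaml(default_scenarios(), tmp_path / "reg.yaml")
        assert scenarios_from_yaml(path) == default_scenarios()


class TestEvaluateScenarios:
    def test_shift_35_rejects_low_marine_and_eel(self):
        flags = {
            e.scenario.name: e.retained for e in evaluate_scenarios(SHIFT_35)
        }
        assert flags["S-AOM-marine-low"] is False
        assert flags["EEL-AOM"] is False

    def test_shift_35_hand_enumeration(self):
        est = {e.scenario.name: e for e in evaluate_scenarios(SHIFT_35)}
        expected = {
            "S-AOM-marine-low": 35.0 / 8.0,
            "EEL-AOM": 35.0 / 16.4,
            "S-AOM-freshwater": 35.0 / 29.0,
            "Fe-AOM": 35.0 / 30.0,
            "N-AOM": 35.0 / 31.0,
            "S-AOM-marine-high": 35.0 / 38.0,
        }
        for name, f in expected.items():
            assert est[name].f_raw == pytest.approx(f, rel=1e-9)
            assert est[name].retained is (f <= 1.0)
            assert est[name].f_capped == pytest.approx(min(f, 1.0), rel=1e-9)

    def test_zero_shift_retains_all_six_at_zero(self):
        est = evaluate_scenarios(shift_of(-50.0, -50.0))
        assert all(e.retained and e.f_raw == 0.0 for e in est)

    def test_negative_shift_flagged_not_raised(self):
        est = evaluate_scenarios(shift_of(-36.0, -36.5))
        # δ_p above the source threshold is the caller's concern; the model
        # itself flags negative fractions instead of raising
        assert all(not e.retained for e in est if e.f_raw < 0.0)

    def test_empty_scenario_collection_rejected(self):
        with pytest.raises(ParameterError):
            evaluate_scenarios(SHIFT_35, scenarios=[])

    def test_retention_depends_only_on_f_raw_and_cap(self):
        est = evaluate_scenarios(SHIFT_35, cap=5.0)
        assert all(e.retained for e in est)  # all f_raw <= 35/8 < 5

    def test_retained_bounds_min_max(self):
        est = evaluate_scenarios(SHIFT_35)
        assert retained_bounds(est) == pytest.approx((35.0 / 38.0, 35.0 / 38.0))
        assert retained_bounds([]) is None
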