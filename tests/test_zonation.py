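"""Zonation labels, isotope-shift extraction and SMTZ detection."""

import itertools
import random

import pytest

from permaom import (
    InsufficientDataError,
    ParameterError,
    ZoneLabel,
    classify_horizons,
    detect_smtz,
    max_isotope_shift,
    mean_isotope_shift,
)
from tests.conftest import make_profile


def delta_profile(deltas, start_depth=10.0, step=1.0):
    return make_profile(
        [
            {"depth_mbsf": start_depth + i * step, "d13c_ch4": d}
            for i, d in enumerate(deltas)
        ]
    )


class TestClassify:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (-35.0, ZoneLabel.OXIDIZED),
            (-70.0, ZoneLabel.SOURCE),
            (-45.0, ZoneLabel.INTERMEDIATE),
            (-37.0, ZoneLabel.INTERMEDIATE),  # thresholds are strict
            (-52.0, ZoneLabel.INTERMEDIATE),
            (None, ZoneLabel.UNCONSTRAINED),
        ],
    )
    def test_threshold_classification(self, delta, expected):
        prof = make_profile([{"depth_mbsf": 1.0, "d13c_ch4": delta}])
        assert classify_horizons(prof)[0].label is expected

    def test_every_record_gets_exactly_one_label(self, c2_noiseless):
        _, profile, _ = c2_noiseless
        labels = classify_horizons(profile)
        assert len(labels) == len(profile)
        assert [l.depth_mbsf for l in labels] == [r.depth_mbsf for r in profile]

    def test_misordered_thresholds_rejected(self, simple_profile):
        with pytest.raises(ParameterError):
            classify_horizons(simple_profile, ox_threshold=-52.0, source_threshold=-37.0)


class TestMaxShift:
    def test_printed_extremes_give_35_permil(self):
        prof = delta_profile([-37.0 + 1e-12, -72.0], start_depth=50.0, step=2.0)
        shift = max_isotope_shift(prof)
        assert shift is not None
        assert shift.shift == pytest.approx(35.0, abs=1e-9)
        assert shift.depth_o == 50.0 and shift.depth_p == 52.0

    def test_no_oxidized_horizon_gives_none(self):
        assert max_isotope_shift(delta_profile([-60.0] * 5)) is None

    def test_source_above_oxidized_does_not_qualify(self):
        # source layer must be subjacent: shallower source is ignored
        prof = delta_profile([-72.0, -35.0])
        assert max_isotope_shift(prof) is None

    def test_matches_exhaustive_pair_search(self):
        rng = random.Random(42)
        for _ in range(20):
            n = rng.randint(4, 12)
            deltas = [rng.uniform(-90.0, -25.0) for _ in range(n)]
            prof = delta_profile(deltas)
            got = max_isotope_shift(prof)
            # independent oracle: enumerate all ordered pairs
            pairs = [
                (a.d13c_ch4 - b.d13c_ch4)
                for a, b in itertools.permutations(prof.records, 2)
                if a.d13c_ch4 > -37.0 and b.d13c_ch4 < -52.0
                and b.depth_mbsf > a.depth_mbsf
            ]
            if not pairs:
                assert got is None
            else:
                assert got.shift == pytest.approx(max(pairs), abs=1e-12)

    def test_row_order_invariance(self):
        rng = random.Random(1)
        deltas = [rng.uniform(-90.0, -25.0) for _ in range(12)]
        rows = [
            {"depth_mbsf": 10.0 + i, "d13c_ch4": d} for i, d in enumerate(deltas)
        ]
        ref = max_isotope_shift(make_profile(rows))
        for _ in range(5):
            rng.shuffle(rows)
            assert max_isotope_shift(make_profile(rows)) == ref

    def test_tie_break_prefers_smallest_separation_then_shallowest(self):
        # two oxidized at -30 (depths 10, 12), two sources at -70 (depths 14, 20)
        prof = make_profile(
            [
                {"depth_mbsf": 10.0, "d13c_ch4": -30.0},
                {"depth_mbsf": 12.0, "d13c_ch4": -30.0},
                {"depth_mbsf": 14.0, "d13c_ch4": -70.0},
                {"depth_mbsf": 20.0, "d13c_ch4": -70.0},
            ]
        )
        shift = max_isotope_shift(prof)
        assert (shift.depth_o, shift.depth_p) == (12.0, 14.0)


class TestMeanShift:
    def test_zone_means_and_depths(self):
        prof = make_profile(
            [
                {"depth_mbsf": 10.0, "d13c_ch4": -30.0},
                {"depth_mbsf": 11.0, "d13c_ch4": -34.0},
                {"depth_mbsf": 20.0, "d13c_ch4": -60.0},
                {"depth_mbsf": 21.0, "d13c_ch4": -70.0},
            ]
        )
        shift = mean_isotope_shift(prof)
        assert shift.delta_o == pytest.approx(-32.0)
        assert shift.delta_p == pytest.approx(-65.0)
        assert shift.shift == pytest.approx(33.0)

    def test_none_when_a_zone_is_empty(self):
        assert mean_isotope_shift(delta_profile([-45.0, -60.0])) is None


class TestSmtz:
    def test_analytic_linear_crossing_is_bracketed(self):
        # sulfate 10→0 mM, methane 0→500 µM linearly over 20–30 mbsf:
        # normalized curves cross at 25 mbsf
        prof = make_profile(
            [
                {"depth_mbsf": 20.0, "sulfate": 10.0, "ch4": 0.0},
                {"depth_mbsf": 24.0, "sulfate": 6.0, "ch4": 200.0},
                {"depth_mbsf": 26.0, "sulfate": 4.0, "ch4": 300.0},
                {"depth_mbsf": 30.0, "sulfate": 0.0, "ch4": 500.0},
            ]
        )
        smtz = detect_smtz(prof)
        assert smtz is not None
        assert 25.0 in smtz
        assert smtz.sulfate_at_top == 6.0
        assert smtz.methane_at_bottom == 300.0

    def test_zero_sulfate_everywhere_gives_none(self):
        prof = make_profile(
            [{"depth_mbsf": d, "sulfate": 0.0, "ch4": 10.0 * d} for d in (1.0, 2.0, 3.0)]
        )
        assert detect_smtz(prof) is None

    def test_parallel_gradients_give_none(self):
        prof = make_profile(
            [{"depth_mbsf": d, "sulfate": d, "ch4": 10.0 * d} for d in (1.0, 2.0, 3.0)]
        )
        assert detect_smtz(prof) is None

    def test_sulfate_below_floor_gives_none(self):
        prof = make_profile(
            [
                {"depth_mbsf": 1.0, "sulfate": 0.5, "ch4": 0.0},
                {"depth_mbsf": 2.0, "sulfate": 0.3, "ch4": 50.0},
                {"depth_mbsf": 3.0, "sulfate": 0.0, "ch4": 100.0},
            ]
        )
        assert detect_smtz(prof, sulfate_floor=1.0) is None
        assert detect_smtz(prof, sulfate_floor=0.1) is not None

    def test_too_few_comeasured_records_raises(self):
        prof = make_profile(
            [
                {"depth_mbsf": 1.0, "sulfate": 10.0, "ch4": 1.0},
                {"depth_mbsf": 2.0, "sulfate": 5.0},  # methane missing
                {"depth_mbsf": 3.0, "sulfate": 1.0, "ch4": 100.0},
            ]
        )
        with pytest.raises(InsufficientDataError):
            detect_smtz(prof)

    def test_interval_inside_profile_depth_range(self, bk2_noiseless):
        _, profile, _ = bk2_noiseless
        smtz = detect_smtz(profile)
        lo, hi = profile.depth_range
        assert smtz is not None
        assert lo <= smtz.top_mbsf < smtz.bottom_mbsf <= hi
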