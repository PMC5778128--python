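"""Methane release and oxidized-carbon budget arithmetic."""

import pytest

from permaom import (
    BudgetInputs,
    ParameterError,
    ValidationError,
    budget_grid,
    grid_extremes,
    methane_release_rate,
    oxidized_carbon,
)
from permaom.budget import CARBON_MOLAR_MASS_G_PER_MOL, budget_inputs_from_yaml

BK2_STYLE = BudgetInputs(
    degradation_rate_m_per_yr=0.053,
    ch4_low_mol_m3=0.1,
    ch4_mean_mol_m3=0.384,
    ch4_high_mol_m3=1.0,
    f_ox_bounds=(0.76, 1.0),
    area_m2=3.0e12,
    porewater_volume_fraction=0.4,
)


class TestRelease:
    def test_dimensional_hand_value(self):
        # 0.053 m/yr × 3e12 m² × 0.4 × 0.384 mol/m³
        release = methane_release_rate(BK2_STYLE, "mean")
        assert release == pytest.approx(0.053 * 3.0e12 * 0.4 * 0.384, rel=1e-12)
        assert release == pytest.approx(2.44224e10, rel=1e-6)

    def test_release_independent_of_f_ox_bounds(self):
        import dataclasses

        other = dataclasses.replace(BK2_STYLE, f_ox_bounds=(0.0, 0.1))
        assert methane_release_rate(other, "mean") == methane_release_rate(
            BK2_STYLE, "mean"
        )

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValidationError):
            BudgetInputs(
                degradation_rate_m_per_yr=0.053,
                ch4_low_mol_m3=0.1,
                ch4_mean_mol_m3=0.4,
                ch4_high_mol_m3=1.0,
                area_m2=0.0,
            )

    def test_unordered_levels_rejected(self):
        with pytest.raises(ValidationError):
            BudgetInputs(
                degradation_rate_m_per_yr=0.05,
                ch4_low_mol_m3=1.0,
                ch4_mean_mol_m3=0.5,
                ch4_high_mol_m3=2.0,
            )

    def test_unknown_level_rejected(self):
        with pytest.raises(ParameterError):
            methane_release_rate(BK2_STYLE, "median")


class TestOxidizedCarbon:
    def test_unit_tracked_hand_value(self):
        # independent dimensional path: mol/yr × g/mol → g/yr → Tg/yr
        release = 2.44224e10
        expected_g_per_yr = release * CARBON_MOLAR_MASS_G_PER_MOL
        assert oxidized_carbon(release, 1.0) == pytest.approx(
            expected_g_per_yr / 1.0e12, rel=1e-12
        )
        assert oxidized_carbon(release, 1.0) == pytest.approx(0.29334, abs=5e-6)

    def test_zero_fraction_gives_zero(self):
        assert oxidized_carbon(1.0e12, 0.0) == 0.0

    def test_linearity_in_release(self):
        assert oxidized_carbon(2.0e10, 0.5) == pytest.approx(
            2.0 * oxidized_carbon(1.0e10, 0.5), rel=1e-12
        )

    @pytest.mark.parametrize("f", [-0.1, 1.1])
    def test_fraction_outside_unit_interval_rejected(self, f):
        with pytest.raises(ParameterError):
            oxidized_carbon(1.0e10, f)


class TestGrid:
    def test_six_cells_match_elementwise_recomputation(self):
        grid = budget_grid(BK2_STYLE)
        assert len(grid) == 6
        f_by_bound = {"min": 0.76, "max": 1.0}
        for cell in grid:
            release = methane_release_rate(BK2_STYLE, cell.concentration_level)
            assert cell.ch4_release_mol_per_yr == pytest.approx(release, rel=1e-12)
            assert cell.oxidized_carbon_tg_per_yr == pytest.approx(
                oxidized_carbon(release, f_by_bound[cell.f_ox_bound]), rel=1e-12
            )

    def test_degenerate_grid_collapses_to_one_value(self):
        inputs = BudgetInputs(
            degradation_rate_m_per_yr=0.01,
            ch4_low_mol_m3=0.5,
            ch4_mean_mol_m3=0.5,
            ch4_high_mol_m3=0.5,
            f_ox_bounds=(0.8, 0.8),
        )
        vals = {c.oxidized_carbon_tg_per_yr for c in budget_grid(inputs)}
        assert len(vals) == 1

    def test_extremes_are_grid_corners_and_bound_every_cell(self):
        grid = budget_grid(BK2_STYLE)
        lo, hi = grid_extremes(grid)
        assert lo == pytest.approx(
            oxidized_carbon(methane_release_rate(BK2_STYLE, "low"), 0.76), rel=1e-12
        )
        assert hi == pytest.approx(
            oxidized_carbon(methane_release_rate(BK2_STYLE, "high"), 1.0), rel=1e-12
        )
        assert all(lo <= c.oxidized_carbon_tg_per_yr <= hi for c in grid)

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "budget.yaml"
        path.write_text(
            yaml.safe_dump(
                {
                    "degradation_rate_m_per_yr": 0.053,
                    "ch4_low_mol_m3": 0.1,
                    "ch4_mean_mol_m3": 0.384,
                    "ch4_high_mol_m3": 1.0,
                    "f_ox_bounds": [0.76, 1.0],
                    "area_m2": 3.0e12,
                    "porewater_volume_fraction": 0.4,
                }
            )
        )
        assert budget_inputs_from_yaml(path) == BK2_STYLE
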