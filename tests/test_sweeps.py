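"""Tests for parameter sweeps and breakeven analysis."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from liftrisk import (
    DamageParams,
    DomainError,
    LiftTask,
    breakeven_curve,
    breakeven_rep_increase,
    breakeven_weight_increase,
    damage_change_grid,
    productivity_scenarios,
    load_moment,
    required_exo_moment,
)


class TestBreakevenRepetitions:
    def test_zero_exo_zero_breakeven(self, params):
        assert breakeven_rep_increase(0.0, params) == 0.0

    def test_lowest_case_series_assistance_needs_79_percent(self, params):
        assert breakeven_rep_increase(15.3, params) == pytest.approx(79.0, abs=0.5)

    def test_highest_case_series_assistance_needs_399_percent(self, params):
        assert breakeven_rep_increase(42.3, params) == pytest.approx(399.0, abs=1.5)

    def test_independent_of_nominal_task(self):
        """The repetition breakeven depends only on the exo moment: the
        root-finder result is the same for any nominal task (identity map)."""
        p = DamageParams(moment_to_load_fn=lambda m: m)
        closed = breakeven_rep_increase(20.0, DamageParams())
        for mass, dist in [(5.0, 0.6), (45.0, 0.6), (22.7, 0.7)]:
            numeric = breakeven_rep_increase(20.0, p, task=LiftTask(mass, dist, 100))
            assert closed == pytest.approx(numeric, rel=1e-9)

    @given(exo=st.floats(0.1, 50.0))
    def test_closed_form_agrees_with_root_finder(self, exo):
        """Closed form vs Brent bisection through a callable moment map."""
        affine = DamageParams()
        callable_map = DamageParams(moment_to_load_fn=lambda m: m)
        closed = breakeven_rep_increase(exo, affine)
        numeric = breakeven_rep_increase(
            exo, callable_map, task=LiftTask(45.0, 0.6, 100)
        )
        assert numeric == pytest.approx(closed, rel=1e-6)

    def test_callable_map_requires_task_and_feasible_exo(self):
        p = DamageParams(moment_to_load_fn=lambda m: m)
        with pytest.raises(DomainError):
            breakeven_rep_increase(10.0, p)
        with pytest.raises(DomainError):
            breakeven_rep_increase(500.0, p, task=LiftTask(45.0, 0.6, 100))


class TestBreakevenWeight:
    def test_zero_exo_zero_breakeven(self, params):
        assert breakeven_weight_increase(0.0, 45.0, 0.6, params) == 0.0

    def test_case_series_1_assistance_is_6_percent_of_45kg(self, params):
        x = breakeven_weight_increase(15.3, 45.0, 0.6, params)
        assert round(x) == 6
        assert round(0.01 * x * 45.0) == 3  # ~3 kg of extra object weight

    @given(
        exo=st.floats(0.1, 50.0),
        mass=st.floats(5.0, 60.0),
        dist=st.floats(0.3, 0.9),
    )
    def test_identity_x_times_M_equals_exo_and_numeric_agrees(self, exo, mass, dist):
        params = DamageParams()
        x = breakeven_weight_increase(exo, mass, dist, params)
        assert 0.01 * x * load_moment(mass, dist) == pytest.approx(exo, rel=1e-9)
        numeric = breakeven_weight_increase(exo, mass, dist, params, numeric=True)
        assert numeric == pytest.approx(x, rel=1e-6)

    def test_zero_nominal_moment_rejected(self, params):
        with pytest.raises(DomainError):
            breakeven_weight_increase(10.0, 0.0, 0.6, params)


class TestRequiredExoMoment:
    @pytest.mark.parametrize(
        "mass,expected", [(5.0, 6.0), (23.0, 27.0), (45.0, 53.0)]
    )
    def test_20pct_weight_increase_by_nominal_mass(self, params, mass, expected):
        req = required_exo_moment(20.0, "weight", mass, 0.6, params)
        assert round(req) == expected

    def test_20pct_repetition_increase_needs_5_nm_any_mass(self, params):
        for mass in (5.0, 23.0, 45.0):
            req = required_exo_moment(20.0, "repetitions", mass, 0.6, params)
            assert round(req) == 5

    def test_weight_requirement_proportional_to_nominal_mass(self, params):
        r5 = required_exo_moment(20.0, "weight", 5.0, 0.6, params)
        r45 = required_exo_moment(20.0, "weight", 45.0, 0.6, params)
        assert r45 / r5 == pytest.approx(9.0, rel=1e-12)

    def test_inverse_of_breakeven(self, params):
        for exo in (5.0, 15.3, 30.0):
            x = breakeven_rep_increase(exo, params)
            assert required_exo_moment(x, "repetitions", 45.0, 0.6, params) == pytest.approx(
                exo, rel=1e-12
            )

    def test_invalid_mode_rejected(self, params):
        with pytest.raises(DomainError):
            required_exo_moment(20.0, "cadence", 45.0, 0.6, params)


class TestGrids:
    def grid(self, params, mode="repetitions", mass=45.0, dist=0.6, reps=1000):
        return damage_change_grid(
            mode,
            LiftTask(mass, dist, reps),
            np.arange(0.0, 51.0, 5.0),
            np.arange(0.0, 101.0, 10.0),
            params,
        )

    def test_origin_cell_is_zero(self, params):
        g = self.grid(params)
        assert g.values[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_both_axes(self, params):
        for mode in ("repetitions", "weight"):
            g = self.grid(params, mode=mode)
            assert np.all(np.diff(g.values, axis=0) <= 1e-9)   # exo axis: down
            assert np.all(np.diff(g.values, axis=1) >= -1e-9)  # increase axis: up

    def test_repetition_grid_independent_of_nominal_mass(self, params):
        g5 = self.grid(params, mass=5.0)
        g23 = self.grid(params, mass=23.0)
        g45 = self.grid(params, mass=45.0)
        np.testing.assert_allclose(g5.values, g23.values, rtol=1e-12)
        np.testing.assert_allclose(g5.values, g45.values, rtol=1e-12)

    def test_grid_invariant_to_nominal_repetition_count(self, params):
        g1 = self.grid(params, reps=100)
        g2 = self.grid(params, reps=5000)
        np.testing.assert_allclose(g1.values, g2.values, rtol=1e-12)

    def test_sign_structure_stable_across_distances(self, params):
        """Within 0.3-0.9 m object-to-hip distance the breakeven structure of
        the repetition grid is unchanged (it cancels out of the ratio)."""
        ref = np.sign(np.round(self.grid(params, dist=0.6).values, 9))
        for dist in (0.3, 0.45, 0.75, 0.9):
            s = np.sign(np.round(self.grid(params, dist=dist).values, 9))
            np.testing.assert_array_equal(ref, s)

    def test_scenario_cell_30nm_20pct_reps(self, params):
        g = damage_change_grid(
            "repetitions",
            LiftTask(22.7, 0.70, 1000),
            np.array([30.0]),
            np.array([20.0]),
            params,
        )
        assert g.values[0, 0] == pytest.approx(-62.0, abs=0.5)

    def test_empty_axes_rejected(self, params):
        with pytest.raises(DomainError):
            damage_change_grid(
                "repetitions", LiftTask(45, 0.6, 100), np.array([]), np.array([0.0]),
                params,
            )

    def test_long_format_roundtrip(self, params):
        g = self.grid(params)
        df = g.to_dataframe()
        assert len(df) == g.values.size
        assert df["damage_change_pct"].iloc[0] == pytest.approx(0.0, abs=1e-12)


class TestBreakevenCurve:
    def test_required_moment_strictly_increasing_with_increase(self, params):
        inc = np.arange(0.0, 101.0, 5.0)
        for mode, mass in (("repetitions", 45.0), ("weight", 23.0)):
            c = breakeven_curve(mode, inc, mass, 0.6, params)
            assert np.all(np.diff(c.required_exo_moments) > 0)


class TestFigure5:
    def test_scenario_table(self, params):
        df = productivity_scenarios(params).set_index("scenario")
        assert df.loc["A", "damage_change_pct"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc["B", "damage_change_pct"] == pytest.approx(-68.0, abs=0.5)
        assert df.loc["C", "damage_change_pct"] == pytest.approx(-62.0, abs=0.5)
        # same-productivity comparison: increasing reps beats increasing weight
        assert df.loc["C", "damage_change_pct"] < df.loc["D", "damage_change_pct"]

    def test_scenario_d_weight_increase_raises_damage(self, params):
        """The log-linear S-N model puts the +20%-weight scenario slightly
        above nominal damage (about +5%); the model's own value, computed
        rather than assumed."""
        df = productivity_scenarios(params).set_index("scenario")
        assert 0.0 < df.loc["D", "damage_change_pct"] < 10.0
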