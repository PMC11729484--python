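"""Unit and property tests for the fatigue-failure damage model."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from liftrisk import (
    ClampWarning,
    DamageCapWarning,
    DamageParams,
    DomainError,
    LiftTask,
    UndefinedComparisonError,
    cumulative_damage,
    effective_moment,
    load_moment,
    per_lift_damage,
    percent_change_damage,
    power_law_damage_ratio,
)


class TestLoadMoment:
    @pytest.mark.parametrize(
        "mass,distance,expected",
        [
            (0.0, 0.6, 0.0),
            (22.7, 0.70, 22.7 * 9.81 * 0.70),  # ~155.9 Nm
            (45.0, 0.60, 45.0 * 9.81 * 0.60),  # ~264.9 Nm
        ],
    )
    def test_mass_times_gravity_times_distance(self, mass, distance, expected):
        assert load_moment(mass, distance) == pytest.approx(expected)

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            load_moment(-1.0, 0.5)
        with pytest.raises(DomainError):
            load_moment(1.0, -0.5)


class TestEffectiveMoment:
    @pytest.mark.parametrize(
        "lm,exo,expected", [(155.9, 30.0, 125.9), (100.0, 0.0, 100.0)]
    )
    def test_subtraction(self, lm, exo, expected):
        assert effective_moment(lm, exo) == pytest.approx(expected)

    def test_over_assistance_clamps_to_zero_with_warning(self):
        with pytest.warns(ClampWarning):
            assert effective_moment(10.0, 50.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(DomainError):
            effective_moment(-1.0, 0.0)
        with pytest.raises(DomainError):
            effective_moment(10.0, -1.0)


class TestPerLiftDamage:
    def test_exponential_ratio_identity_across_moment_grid(self, params):
        """d(M-m)/d(M) = 10^(-slope*m) to machine precision, any M >= m."""
        for m in (5.0, 15.3, 30.0, 42.3):
            for M in np.linspace(m, 400.0, 40):
                ratio = per_lift_damage(M - m, params) / per_lift_damage(M, params)
                assert ratio == pytest.approx(
                    10.0 ** (-params.sn_slope * m), rel=1e-12
                )

    def test_strictly_increasing_in_moment(self, params):
        grid = np.linspace(0.0, 450.0, 200)
        d = per_lift_damage(grid, params)
        assert np.all(np.diff(d) > 0)
        assert np.all((d > 0) & (d <= 1))

    def test_thirty_nm_reduction_is_68_percent(self, params):
        """A 30 Nm moment offset cuts per-lift damage by 68% at the default slope."""
        ratio = per_lift_damage(125.9, params) / per_lift_damage(155.9, params)
        assert ratio == pytest.approx(0.32, abs=0.005)

    def test_default_slope_recovered_from_breakeven_constraints(self, params):
        """Least-squares slope through the two breakeven anchor points
        (15.3 Nm -> 1.79x damage, 42.3 Nm -> 4.99x) matches the default
        within 2% relative."""
        x = np.array([15.3, 42.3])
        y = np.array([math.log10(1.79), math.log10(4.99)])
        fitted = float(np.sum(x * y) / np.sum(x * x))
        assert fitted == pytest.approx(params.sn_slope, rel=0.02)

    def test_nf_below_one_capped_with_warning(self):
        p = DamageParams(sn_intercept=1.0, sn_slope=0.1)
        with pytest.warns(DamageCapWarning):
            assert per_lift_damage(100.0, p) == 1.0

    def test_affine_moment_to_load_offset_cancels_in_ratio(self):
        base = DamageParams()
        shifted = DamageParams(moment_to_load_offset=50.0)
        r0 = per_lift_damage(100.0, base) / per_lift_damage(130.0, base)
        r1 = per_lift_damage(100.0, shifted) / per_lift_damage(130.0, shifted)
        assert r0 == pytest.approx(r1, rel=1e-12)

    def test_negative_moment_rejected(self, params):
        with pytest.raises(DomainError):
            per_lift_damage(-1.0, params)


class TestCumulativeDamage:
    def test_zero_repetitions_zero_damage(self, params):
        task = LiftTask(45.0, 0.6, 0)
        assert cumulative_damage(task, 0.0, params).cumulative_damage == 0.0

    @given(reps=st.integers(1, 5000), k=st.sampled_from([2, 4, 8, 16]))
    def test_exactly_linear_in_repetitions(self, reps, k):
        """Power-of-two multiples scale exactly even in floating point."""
        params = DamageParams()
        d1 = cumulative_damage(LiftTask(45.0, 0.6, reps), 10.0, params)
        dk = cumulative_damage(LiftTask(45.0, 0.6, k * reps), 10.0, params)
        assert dk.cumulative_damage == k * d1.cumulative_damage

    @given(reps=st.integers(1, 5000), k=st.integers(2, 9))
    def test_linear_in_repetitions_general_multiplier(self, reps, k):
        params = DamageParams()
        d1 = cumulative_damage(LiftTask(45.0, 0.6, reps), 10.0, params)
        dk = cumulative_damage(LiftTask(45.0, 0.6, k * reps), 10.0, params)
        assert dk.cumulative_damage == pytest.approx(
            k * d1.cumulative_damage, rel=1e-15
        )

    def test_oracle_sum_of_per_lift_damages(self, params):
        """Bout damage equals the brute-force lift-by-lift sum."""
        task = LiftTask(30.0, 0.65, 137)
        res = cumulative_damage(task, 12.0, params)
        brute = sum(
            per_lift_damage(res.effective_moment, params)
            for _ in range(task.repetitions)
        )
        assert res.cumulative_damage == pytest.approx(brute, rel=1e-12)

    @given(
        mass=st.floats(1.0, 60.0),
        distance=st.floats(0.3, 0.9),
        exo=st.floats(0.0, 50.0),
    )
    def test_monotone_in_task_and_exo(self, mass, distance, exo):
        params = DamageParams()
        base = cumulative_damage(LiftTask(mass, distance, 100), exo, params)
        heavier = cumulative_damage(LiftTask(mass + 5, distance, 100), exo, params)
        farther = cumulative_damage(LiftTask(mass, distance + 0.05, 100), exo, params)
        assisted = cumulative_damage(LiftTask(mass, distance, 100), exo + 5, params)
        assert heavier.cumulative_damage >= base.cumulative_damage
        assert farther.cumulative_damage >= base.cumulative_damage
        assert assisted.cumulative_damage <= base.cumulative_damage

    def test_scenario_exo_reduces_damage_68_percent(self, params, scenario_task):
        without = cumulative_damage(scenario_task, 0.0, params).cumulative_damage
        with_exo = cumulative_damage(scenario_task, 30.0, params).cumulative_damage
        assert 100.0 * (1 - with_exo / without) == pytest.approx(68.0, abs=0.5)


class TestPercentChange:
    @pytest.mark.parametrize(
        "new,old,expected", [(0.5, 1.0, -50.0), (1.0, 1.0, 0.0), (1.5, 1.0, 50.0)]
    )
    def test_convention(self, new, old, expected):
        assert percent_change_damage(new, old) == pytest.approx(expected)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedComparisonError):
            percent_change_damage(1.0, 0.0)


class TestPowerLawRatio:
    @pytest.mark.parametrize(
        "ratio,C,expected",
        [(1.0, 4.0, 1.0), (1.0, 9.0, 1.0), (0.9, 4.0, 0.6561), (0.9, 9.0, 0.9**9)],
    )
    def test_values(self, ratio, C, expected):
        assert power_law_damage_ratio(ratio, C) == pytest.approx(expected)

    def test_exponent_outside_tissue_range_warns(self):
        with pytest.warns(UserWarning):
            power_law_damage_ratio(0.9, 12.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(DomainError):
            power_law_damage_ratio(0.0, 5.0)


class TestValidation:
    def test_lift_task_invariants(self):
        with pytest.raises(DomainError):
            LiftTask(-1.0, 0.5, 10)
        with pytest.raises(DomainError):
            LiftTask(1.0, 0.5, -1)
        with pytest.raises(DomainError):
            LiftTask(1.0, 0.5, 10, period=0.0)

    def test_damage_params_invariants(self):
        with pytest.raises(DomainError):
            DamageParams(sn_slope=0.0)
        with pytest.raises(DomainError):
            DamageParams(gravity=-9.81)
        with pytest.warns(UserWarning):
            DamageParams(power_exponent_C=3.0)
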