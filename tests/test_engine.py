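"""Fortification formulas, flooring, clustering, and the scenario grid."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fortiplan import (
    FortificationPlan,
    InfeasibleScenarioError,
    apply_fortification,
    Scenario,
    SeasonalModel,
    SerumTrajectory,
    cluster_plan,
    constant_fortification,
    constant_plan,
    generate_trajectory,
    scenario_grid,
    seasonal_plan,
    varying_fortification,
)


class TestConstantFortification:
    def test_published_bread_example(self):
        # mean bread consumer, IOM 15 ug target, current intake 3.1 + 0.3 ug
        assert constant_fortification(15.0, 3.4, 180.0) == pytest.approx(
            6.44, abs=0.005
        )

    def test_zero_deficit_gives_zero_level(self):
        assert constant_fortification(15.0, 15.0, 180.0) == 0.0

    def test_ul_target(self):
        assert constant_fortification(100.0, 3.4, 180.0) == pytest.approx(
            53.67, abs=0.005
        )

    def test_intake_above_target_floors_to_zero(self):
        assert constant_fortification(15.0, 40.0, 180.0) == 0.0

    def test_zero_consumption_is_infeasible(self):
        with pytest.raises(InfeasibleScenarioError, match="nonzero consumption"):
            constant_fortification(15.0, 3.4, 0.0)

    @given(
        i_r=st.floats(5, 100),
        i_a=st.floats(0, 4.9),
        f_i=st.floats(10, 1000),
        bump=st.floats(0.1, 50),
    )
    def test_monotonicity_on_unfloored_branch(self, i_r, i_a, f_i, bump):
        base = constant_fortification(i_r, i_a, f_i)
        assert constant_fortification(i_r + bump, i_a, f_i) > base
        assert constant_fortification(i_r, i_a, f_i + bump) < base
        if i_a + bump < i_r:
            assert constant_fortification(i_r, i_a + bump, f_i) < base


class TestVaryingFortification:
    def test_published_january_example(self, trajectory):
        levels = varying_fortification(75.0, trajectory, 2.32, 180.0)
        assert levels[0] == pytest.approx(11.30, abs=0.005)

    def test_baseline_above_target_floors_to_zero(self, trajectory):
        # July baseline 62.2 nmol/L exceeds the 50 nmol/L target
        levels = varying_fortification(50.0, trajectory, 2.32, 180.0)
        assert levels[6] == 0.0

    def test_direct_formula_value(self):
        flat = SerumTrajectory(values=(45.0,) * 12)
        levels = varying_fortification(50.0, flat, 2.32, 100.0)
        assert levels[0] == pytest.approx(2.155, abs=0.0005)

    def test_constant_baseline_gives_equal_levels(self):
        flat = generate_trajectory(SeasonalModel(annual_mean=45.0, amplitude=0.0))
        levels = varying_fortification(75.0, flat, 2.32, 180.0)
        assert len(set(levels)) == 1

    def test_flooring_never_emits_negative(self, trajectory):
        for target in (10.0, 30.0, 50.0, 75.0):
            assert (varying_fortification(target, trajectory, 2.32, 180.0) >= 0).all()

    def test_bad_inputs_rejected(self, trajectory):
        with pytest.raises(InfeasibleScenarioError):
            varying_fortification(75.0, trajectory, 2.32, 0.0)
        with pytest.raises(ValueError, match="conversion factor"):
            varying_fortification(75.0, trajectory, -1.0, 180.0)


class TestOracleEquivalence:
    """The engine must agree with direct one-line arithmetic on random draws."""

    def test_all_three_formulas(self, rng=np.random.default_rng(20260929)):
        n = 1000
        i_r = rng.uniform(5, 100, n)
        i_a = rng.uniform(0, 10, n)
        f_i = rng.uniform(10, 1200, n)
        l_r = rng.uniform(40, 90, n)
        l_a = rng.uniform(10, 80, n)
        cf = rng.uniform(0.5, 4.0, n)
        level = rng.uniform(0, 20, n)
        for k in range(n):
            fc = constant_fortification(i_r[k], i_a[k], f_i[k])
            assert fc == pytest.approx(max(0.0, (i_r[k] - i_a[k]) * 100 / f_i[k]), rel=1e-12)
            flat = SerumTrajectory(values=(l_a[k],) * 12)
            fv = varying_fortification(l_r[k], flat, cf[k], f_i[k])[0]
            assert fv == pytest.approx(
                max(0.0, (l_r[k] - l_a[k]) * 100 / (cf[k] * f_i[k])), rel=1e-12
            )
            l_n = l_a[k] + cf[k] * f_i[k] * level[k] / 100
            plan = FortificationPlan(
                carrier="custom", mode="constant", monthly_levels=(level[k],) * 12
            )
            resp = apply_fortification(flat, plan, f_i=f_i[k], c_f=cf[k])
            assert resp.new_values[0] == pytest.approx(l_n, rel=1e-12)


class TestClusterPlan:
    def test_summer_cluster_is_may_to_september(self, trajectory):
        levels = varying_fortification(50.0, trajectory, 2.32, 180.0)
        plan = cluster_plan(levels, carrier="bread")
        assert plan.summer_months == frozenset({5, 6, 7, 8, 9})
        assert all(plan.level(m) == 0.0 for m in (5, 6, 7, 8, 9))

    def test_winter_level_is_trough_month_requirement(self, trajectory):
        levels = varying_fortification(75.0, trajectory, 2.32, 180.0)
        plan = cluster_plan(levels, carrier="bread")
        # January (the serum trough) has the largest deficit of all 12 months
        assert plan.winter_level == pytest.approx(max(levels))
        assert plan.winter_level == pytest.approx(levels[0])

    def test_all_zero_input(self):
        plan = cluster_plan([0.0] * 12)
        assert plan.winter_level == 0.0
        assert plan.summer_months == frozenset(range(1, 13))
        assert plan.winter_months == frozenset()

    def test_circular_run_spans_december_january(self):
        levels = [0.0, 0.0, 1.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0]
        plan = cluster_plan(levels)
        assert plan.summer_months == frozenset({11, 12, 1, 2})
        assert plan.winter_level == 2.0

    def test_mean_aggregate_flag(self):
        levels = [4.0, 2.0] + [0.0] * 10
        plan = cluster_plan(levels, aggregate="mean")
        assert plan.winter_level == pytest.approx(3.0)

    def test_winter_months_guarantee_target(self, trajectory):
        """Clustered winter level never undershoots any month's requirement."""
        for target in (50.0, 60.0, 75.0):
            levels = varying_fortification(target, trajectory, 2.32, 180.0)
            plan = cluster_plan(levels)
            for m in plan.winter_months:
                assert plan.level(m) >= levels[m - 1] - 1e-12


@pytest.fixture(scope="module")
def grid(params, trajectory):
    return scenario_grid(params, trajectory)


class TestScenarioGrid:
    def test_constant_mode_has_81_cells(self, grid):
        assert len(grid[grid["mode"] == "constant"]) == 81

    def test_seasonal_mode_covers_both_serum_targets(self, grid):
        seasonal = grid[grid["mode"] == "seasonal"]
        assert set(seasonal["target_label"]) == {"serum50", "serum75"}
        # 3 carriers x 3 x 3 percentiles x 2 targets x 12 months
        assert len(seasonal) == 648

    def test_juice_p5_cells_flagged_infeasible(self, grid):
        cells = grid[(grid["carrier"] == "juice") & (grid["carrier_percentile"] == "p5")]
        assert not cells["feasible"].any()
        assert cells["level_ug_per_100g"].isna().all()

    def test_dotted_box_cell_matches_worked_example(self, grid):
        cell = grid[
            (grid["carrier"] == "bread")
            & (grid["mode"] == "constant")
            & (grid["target_label"] == "IOM")
            & (grid["vitd_percentile"] == "mean")
            & (grid["carrier_percentile"] == "mean")
        ]
        assert len(cell) == 1
        assert cell["level_ug_per_100g"].iloc[0] == pytest.approx(6.44, abs=0.005)

    def test_all_feasible_levels_non_negative(self, grid):
        feasible = grid[grid["feasible"]]
        assert (feasible["level_ug_per_100g"] >= 0).all()


def test_plan_builders_reject_wrong_target_kind(params, trajectory):
    intake_target = params.target("IOM")
    serum_target = params.target("serum75")
    with pytest.raises(ValueError, match="serum target"):
        seasonal_plan(params, "bread", Scenario("mean", "mean", intake_target), trajectory)
    with pytest.raises(ValueError, match="intake target"):
        constant_plan(params, "bread", Scenario("mean", "mean", serum_target))
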