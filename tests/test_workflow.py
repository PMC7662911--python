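"""Assessment, three-step optimization and evaluation reporting."""

import numpy as np
import pytest

from rcfopt.core import check_constraints
from rcfopt.mia import MIAParams
from rcfopt.synthetic import ScenarioSpec, generate_scenario
from rcfopt.workflow import (
    adjust_scales,
    assess_current,
    evaluation_report,
    gini_coefficient,
    identify_unreasonable,
    min_new_facilities,
    residual_instance,
    select_best_count,
    sweep_new_count,
    three_step_plan,
)


@pytest.fixture(scope="module")
def district():
    return generate_scenario(ScenarioSpec(seed=11))


@pytest.fixture(scope="module")
def plan(district):
    instance, existing = district
    params = MIAParams(p=existing.open_sites.size, pop_size=30, t_max=80, seed=11)
    return three_step_plan(instance, existing, mia_params=params)


class TestAssessment:
    def test_target_beds_arithmetic(self, district):
        instance, existing = district
        report = assess_current(instance, existing, target_rate=0.025)
        elderly = sum(c.elderly for c in instance.centers)
        assert report.target_beds == pytest.approx(0.025 * elderly)
        assert report.total_bed_deficit == pytest.approx(
            max(0.0, report.target_beds - existing.total_beds)
        )

    def test_study_scale_target(self):
        # 2.5 beds per 100 elderly on a 326,520-strong elderly population
        assert 0.025 * 326520 == pytest.approx(8163)

    def test_balanced_facility_has_zero_gap(self, district):
        instance, _ = district
        from rcfopt.core import size_beds_to_demand

        balanced = size_beds_to_demand(instance, [0, 5, 9])
        report = assess_current(instance, balanced, beta=None)
        assert report.facility_gap == pytest.approx(np.zeros(3), abs=1e-9)

    def test_share_below_target_in_unit_interval(self, district):
        instance, existing = district
        report = assess_current(instance, existing)
        assert 0.0 <= report.share_below_target <= 1.0


class TestIdentifyUnreasonable:
    def test_infinite_tolerance_flags_nothing(self, district):
        instance, existing = district
        params = MIAParams(p=existing.open_sites.size, pop_size=20, t_max=30, seed=1)
        flagged, optimal = identify_unreasonable(
            instance, existing, mia_params=params, distance_tolerance=np.inf
        )
        assert flagged.size == 0
        assert optimal.size == existing.open_sites.size

    def test_flagged_facilities_are_open_and_redundant(self, district):
        instance, existing = district
        params = MIAParams(p=existing.open_sites.size, pop_size=30, t_max=80, seed=11)
        flagged, _ = identify_unreasonable(instance, existing, mia_params=params)
        assert set(flagged).issubset(set(existing.open_sites))


class TestAdjustScales:
    def test_all_within_cap_leaves_nothing_unmet(self, district):
        instance, _ = district
        retained = np.arange(instance.n_sites)  # every site open: tiny loads
        beds, unmet = adjust_scales(instance, retained, cap=10000)
        assert unmet.sum() == 0
        assert beds.sum() == instance.total_demand

    def test_overflow_is_reported_as_unmet(self, district):
        instance, _ = district
        beds, unmet = adjust_scales(instance, np.array([0]), cap=300)
        assert beds[0] == 300
        assert unmet.sum() == instance.total_demand - 300

    def test_unmet_never_exceeds_center_demand(self, district):
        instance, existing = district
        _, unmet = adjust_scales(instance, existing.open_sites[:4], cap=300)
        assert np.all(unmet <= instance.demand + 1e-9)
        assert np.all(unmet >= 0)


class TestMinNewFacilities:
    @pytest.mark.parametrize(
        "unmet,cap,expected", [(1193, 300, 4), (0, 300, 0), (301, 300, 2), (300, 300, 1)]
    )
    def test_ceiling_rule(self, unmet, cap, expected):
        assert min_new_facilities(unmet, cap) == expected

    def test_nonpositive_cap_rejected(self):
        with pytest.raises(ValueError):
            min_new_facilities(100, 0)


class TestSweep:
    def test_argmin_on_published_style_row(self):
        counts = [4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14]
        values = [0.6722, 0.6323, 0.6012, 0.6283, 0.6501, 0.6766,
                  0.7149, 0.7364, 0.7626, 0.7943, 0.8243]
        assert select_best_count(counts, values) == 6

    def test_single_count_returned(self):
        assert select_best_count([5], [0.7]) == 5

    def test_sweep_table_covers_range(self, district):
        instance, existing = district
        _, unmet = adjust_scales(instance, existing.open_sites, cap=300)
        if unmet.sum() == 0:
            pytest.skip("no unmet demand on this seed")
        sub, _, _ = residual_instance(instance, unmet, exclude_sites=existing.open_sites)
        params = MIAParams(p=1, pop_size=15, t_max=25, seed=2)
        n_min = min_new_facilities(unmet.sum(), 300)
        table, p_star, enc = sweep_new_count(sub, range(n_min, n_min + 3), params)
        assert table["p"].tolist() == list(range(n_min, n_min + 3))
        assert p_star in table["p"].tolist()
        assert enc[p_star].size == p_star


class TestGini:
    def test_equal_values_score_zero(self):
        assert gini_coefficient(np.array([2.0, 2.0, 2.0])) == pytest.approx(0.0)

    def test_two_point_extreme(self):
        assert gini_coefficient(np.array([0.0, 1.0])) == pytest.approx(0.5)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.1, 5.0, 20)
        w = rng.uniform(1.0, 10.0, 20)
        assert gini_coefficient(3.3 * x, w) == pytest.approx(gini_coefficient(x, w))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            gini_coefficient(np.zeros(3))

    def test_bounded_below_one(self):
        x = np.array([0.0] * 99 + [100.0])
        assert 0.9 < gini_coefficient(x) < 1.0


class TestThreeStepPlan:
    def test_final_configuration_feasible_and_serves_all_demand(self, district, plan):
        instance, _ = district
        assert check_constraints(instance, plan.final_config).feasible
        assert plan.final_config.total_beds == instance.total_demand

    def test_new_beds_cover_unmet_demand_within_cap(self, plan):
        if plan.unmet_total > 0:
            assert plan.new_beds.sum() == pytest.approx(plan.unmet_total)
            assert np.all(plan.new_beds <= 300)
            assert plan.p_star >= min_new_facilities(plan.unmet_total, 300)

    def test_retained_and_flagged_partition_existing(self, district, plan):
        _, existing = district
        combined = np.sort(np.concatenate([plan.retained, plan.flagged]))
        assert np.array_equal(combined, existing.open_sites)


class TestEvaluationReport:
    def test_identical_configurations_show_zero_change(self, district):
        instance, existing = district
        report = evaluation_report(instance, existing, existing)
        assert report.table["change_pct"].to_numpy() == pytest.approx(0.0, abs=1e-9)

    def test_profit_change_matches_relative_difference(self):
        # mean profit rising 111,785 -> 145,120 is a 29.82% improvement
        assert (145120 - 111785) / 111785 * 100 == pytest.approx(29.82, abs=0.01)

    def test_gini_reduction_matches_relative_difference(self):
        assert (0.5563 - 0.1225) / 0.5563 * 100 == pytest.approx(77.98, abs=0.01)

    def test_planted_defects_improve_after_optimization(self, district, plan):
        instance, existing = district
        report = evaluation_report(instance, existing, plan.final_config)
        table = report.table.set_index("metric")
        for metric in ("equity", "gini", "travel_cost_per_capita"):
            assert table.loc[metric, "change_pct"] > 0
        assert 0.0 <= report.ratio_share_after <= 1.0
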