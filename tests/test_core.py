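"""Domain types, instance validation, allocation and constraint checking."""

import numpy as np
import pytest

from rcfopt.core import (
    CandidateSite,
    CostParameters,
    FacilityConfiguration,
    PopulationCenter,
    allocate_nearest,
    build_instance,
    check_constraints,
    clamp_distances,
    effective_distance,
    size_beds_to_demand,
)


def make_centers(demands, elderly_factor=40):
    return [
        PopulationCenter(f"c{i}", (float(i), 0.0), int(w) * elderly_factor, int(w))
        for i, w in enumerate(demands)
    ]


def make_sites(n):
    return [CandidateSite(f"s{j}", (float(j), 1.0)) for j in range(n)]


class TestTypes:
    def test_center_rejects_demand_above_elderly(self):
        with pytest.raises(ValueError):
            PopulationCenter("c", (0, 0), elderly=10, demand=11)

    def test_center_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            PopulationCenter("c", (0, 0), elderly=-1, demand=0)

    def test_site_requires_positive_capacity(self):
        with pytest.raises(ValueError):
            CandidateSite("s", (0, 0), max_beds=0)

    def test_costs_require_margin(self):
        with pytest.raises(ValueError):
            CostParameters(charge=1000.0, cost=1500.0)
        assert CostParameters().margin == 800.0


class TestBuildInstance:
    def test_micro_instance_totals(self, m1):
        assert m1.total_demand == 30
        assert m1.n_centers == m1.n_sites == 2

    def test_single_pair_is_valid(self):
        inst = build_instance(make_centers([5]), make_sites(1), [[500.0]])
        assert inst.n_centers == inst.n_sites == 1

    @pytest.mark.parametrize("bad_d", [[[0.0, 1.0]], [[-5.0, 1.0]], [[np.inf, 1.0]]])
    def test_nonpositive_or_nonfinite_distance_rejected(self, bad_d):
        with pytest.raises(ValueError, match="positive"):
            build_instance(make_centers([5]), make_sites(2), bad_d)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            build_instance(make_centers([5, 5]), make_sites(2), [[1.0, 2.0]])

    def test_zero_total_demand_rejected(self):
        centers = [PopulationCenter("c0", (0, 0), 10, 0)]
        with pytest.raises(ValueError, match="W"):
            build_instance(centers, make_sites(1), [[100.0]])

    def test_clamp_lifts_small_distances(self):
        out = clamp_distances(np.array([[0.0, 0.5], [2.0, 3.0]]), floor=1.0)
        assert out.min() == 1.0
        assert out[1, 1] == 3.0


class TestEffectiveDistance:
    @pytest.mark.parametrize(
        "shortest,dwells,speed,expected",
        [
            (1000.0, [], 7.0, 1000.0),
            (1000.0, [30.0, 30.0], 5.0, 1300.0),
            (0.0, [10.0], 2.0, 20.0),
        ],
    )
    def test_dwell_conversion(self, shortest, dwells, speed, expected):
        assert effective_distance(shortest, dwells, speed) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_distance(-1.0, [], 5.0)
        with pytest.raises(ValueError):
            effective_distance(10.0, [-1.0], 5.0)
        with pytest.raises(ValueError):
            effective_distance(10.0, [], 0.0)


class TestAllocateNearest:
    def test_each_center_gets_its_near_site(self, m1):
        z = allocate_nearest(m1, [0, 1])
        assert z.tolist() == [[1, 0], [0, 1]]

    def test_single_open_site_takes_all(self, m1):
        z = allocate_nearest(m1, [1])
        assert z[:, 1].tolist() == [1, 1]

    def test_tie_goes_to_lowest_site_index(self):
        inst = build_instance(make_centers([5]), make_sites(2), [[700.0, 700.0]])
        z = allocate_nearest(inst, [0, 1])
        assert z.tolist() == [[1, 0]]

    def test_no_open_site_is_an_error(self, m1):
        with pytest.raises(ValueError):
            allocate_nearest(m1, [])

    def test_assigned_distance_is_minimal(self, district):
        instance, config = district
        z = allocate_nearest(instance, config.open_sites)
        sub = instance.distances[:, config.open_sites]
        assigned = (instance.distances * z).sum(axis=1)
        assert np.allclose(assigned, sub.min(axis=1))


class TestSizeBedsToDemand:
    def test_micro_beds_follow_demand(self, m1_nearest):
        assert m1_nearest.beds.tolist() == [10.0, 20.0]
        assert m1_nearest.total_beds == 30.0

    def test_single_site_takes_everything(self, m1):
        config = size_beds_to_demand(m1, [0])
        assert config.beds.tolist() == [30.0, 0.0]

    @pytest.mark.parametrize("seed", range(5))
    def test_conservation_total_beds_equal_total_demand(self, seed):
        from tests.conftest import random_instance_config

        instance, config = random_instance_config(seed)
        assert config.total_beds == instance.total_demand


class TestCheckConstraints:
    def test_feasible_configuration_all_zero(self, m1, m1_nearest):
        report = check_constraints(m1, m1_nearest)
        assert report.feasible
        assert report.magnitudes.tolist() == [0, 0, 0, 0]

    def test_wrong_declared_count(self, m1, m1_nearest):
        bad = FacilityConfiguration(
            open=m1_nearest.open, beds=m1_nearest.beds,
            allocation=m1_nearest.allocation, p=3,
        )
        report = check_constraints(m1, bad)
        assert report.count == 1
        assert not report.feasible

    def test_capacity_overflow_magnitude(self, m1, m1_nearest):
        bad = FacilityConfiguration(
            open=m1_nearest.open, beds=np.array([301.0, 20.0]),
            allocation=m1_nearest.allocation, p=2,
        )
        assert check_constraints(m1, bad).capacity == 1.0

    def test_open_site_without_beds_is_a_capacity_violation(self, m1, m1_nearest):
        bad = FacilityConfiguration(
            open=m1_nearest.open, beds=np.array([30.0, 0.0]),
            allocation=m1_nearest.allocation, p=2,
        )
        assert check_constraints(m1, bad).capacity == 1.0

    def test_single_perturbations_hit_single_families(self, m1, m1_nearest):
        # close an allocated site: linkage violation only
        closed = FacilityConfiguration(
            open=np.array([1, 0]), beds=np.array([10.0, 20.0]),
            allocation=m1_nearest.allocation, p=1,
        )
        report = check_constraints(m1, closed)
        assert report.linkage == 1
        assert report.coverage == 0
        # unserved center row: coverage violation only
        z = m1_nearest.allocation.copy()
        z[1] = 0
        unserved = FacilityConfiguration(
            open=m1_nearest.open, beds=m1_nearest.beds, allocation=z, p=2
        )
        report = check_constraints(m1, unserved)
        assert report.coverage == 1
        assert report.linkage == 0
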