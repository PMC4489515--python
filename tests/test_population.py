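import numpy as np
import pytest
from scipy import stats

import otternet as ot
from otternet.errors import CapacityError, ParameterError
from otternet.population import (_truncated_positive_normal,
                                 assign_female_cores, draw_population_size,
                                 init_otter_states, place_otters)


class TestActivityThreshold:
    def test_field_estimate_ratio(self):
        # mean active : mean inactive hours, printed as 0.122
        assert abs(ot.compute_activity_threshold(1.433, 11.692)
                   - 0.122) < 1e-3

    @pytest.mark.parametrize("a,b,expected", [(1, 1, 1.0), (2, 8, 0.25)])
    def test_simple_ratios(self, a, b, expected):
        assert ot.compute_activity_threshold(a, b) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            ot.compute_activity_threshold(0, 5)


class TestPopulationSize:
    def test_extrapolation_arithmetic(self):
        p = ot.InitParams(density_min=60, density_max=60)
        study, total = draw_population_size(p, np.random.default_rng(0))
        assert study == 60
        assert total == 60 + round(60 * 0.585) == 95

    def test_zero_factor(self):
        p = ot.InitParams(out_of_area_factor=0.0)
        study, total = draw_population_size(p, np.random.default_rng(1))
        assert total == study

    def test_uniform_mean(self):
        p = ot.InitParams()
        rng = np.random.default_rng(2)
        draws = [draw_population_size(p, rng)[0] for _ in range(10_000)]
        se = np.std(draws, ddof=1) / 100.0
        assert abs(np.mean(draws) - 66.5) < 2.58 * se
        assert min(draws) >= 55 and max(draws) <= 78


class TestInitialStates:
    def test_sex_ratio_monte_carlo(self):
        otters = init_otter_states(10_000, ot.InitParams(),
                                   np.random.default_rng(3))
        frac = np.mean([o.sex == "male" for o in otters])
        assert abs(frac - 0.69) < 2.58 * np.sqrt(0.69 * 0.31 / 10_000)

    def test_zero_threshold_all_inactive(self):
        p = ot.InitParams(activity_threshold=0.0)
        otters = init_otter_states(200, p, np.random.default_rng(4))
        assert all(o.activity == "inactive" for o in otters)

    def test_clock_bounds(self):
        otters = init_otter_states(5_000, ot.InitParams(),
                                   np.random.default_rng(5))
        for o in otters:
            if o.activity == "active":
                assert o.hours_in_state in (0, 1, 2)   # round(U(0, 1.88))
            else:
                assert 0 <= o.hours_in_state <= 15
            assert 0 <= o.hours_since_defecation <= 5


class TestFemaleCores:
    def test_truncated_normal_moments(self):
        rng = np.random.default_rng(6)
        draws = np.array([_truncated_positive_normal(4000.0, 2000.0, rng)
                          for _ in range(10_000)])
        assert (draws > 0).all()
        # closed-form moment of a normal truncated at zero
        a = (0.0 - 4000.0) / 2000.0
        expected = stats.truncnorm.mean(a, np.inf, loc=4000.0, scale=2000.0)
        se = draws.std(ddof=1) / 100.0
        assert abs(draws.mean() - expected) < 2.58 * se

    def test_two_cores_disjoint(self, latrine_rich_net):
        net = latrine_rich_net
        females = [ot.OtterState(id=i, sex="female", activity="inactive",
                                 hours_in_state=0, hours_since_defecation=0)
                   for i in range(2)]
        assign_female_cores(net, females, ot.InitParams(),
                            np.random.default_rng(7))
        (c1, l1), (c2, l2) = [(f.home_center, f.core_length_m)
                              for f in females]
        d = ot.network_distance(net, c1, c2)
        assert d >= (l1 + l2) / 2.0

    def test_single_female_succeeds(self):
        net, _, _ = ot.toy_line_world(100, latrine_ids=[50])
        f = ot.OtterState(id=0, sex="female", activity="inactive",
                          hours_in_state=0, hours_since_defecation=0)
        assign_female_cores(net, [f], ot.InitParams(),
                            np.random.default_rng(8))
        assert f.home_center == 50
        assert f.core_length_m > 0

    def test_capacity_error_when_overfull(self):
        net, _, _ = ot.toy_line_world(30, latrine_ids=[15])
        females = [ot.OtterState(id=i, sex="female", activity="inactive",
                                 hours_in_state=0, hours_since_defecation=0)
                   for i in range(2)]
        p = ot.InitParams(max_placement_attempts=200)
        with pytest.raises(CapacityError):
            assign_female_cores(net, females, p, np.random.default_rng(9))


class TestPlacement:
    def test_all_on_latrine_grade_habitat(self, small_synthetic_net):
        # a 40-km coastline hosts a proportionally smaller population
        net = small_synthetic_net
        rng = np.random.default_rng(10)
        otters, study_n = ot.initialize_population(
            net, ot.InitParams(density_min=8, density_max=12), rng)
        for o in otters:
            assert net.mep[o.position] > 0.464
        # study-area subpopulation placed inside, remainder outside
        for k, o in enumerate(otters):
            assert net.in_study_area[o.position] == (k < study_n)

    def test_single_latrine_point(self):
        net, _, _ = ot.toy_line_world(50, latrine_ids=[20])
        otters = init_otter_states(5, ot.InitParams(male_fraction=1.0),
                                   np.random.default_rng(11))
        place_otters(net, otters, ot.InitParams(), np.random.default_rng(11))
        assert all(o.position == 20 for o in otters)

    def test_uniform_placement(self):
        # male placement is uniform over eligible points (chi-square)
        net, _, _ = ot.toy_line_world(60, latrine_ids=list(range(10, 20)))
        otters = init_otter_states(10_000, ot.InitParams(male_fraction=1.0),
                                   np.random.default_rng(12))
        place_otters(net, otters, ot.InitParams(), np.random.default_rng(12))
        counts = np.bincount([o.position for o in otters],
                             minlength=60)[10:20]
        chi2 = ((counts - 1000.0) ** 2 / 1000.0).sum()
        assert chi2 < stats.chi2.ppf(0.999, df=9)

    def test_no_core_overlap_after_full_init(self, small_synthetic_net):
        net = small_synthetic_net
        otters, _ = ot.initialize_population(
            net, ot.InitParams(density_min=8, density_max=8),
            np.random.default_rng(13))
        females = [o for o in otters if o.sex == "female"]
        for i, a in enumerate(females):
            for b in females[i + 1:]:
                d = ot.network_distance(net, a.home_center, b.home_center)
                assert d >= (a.core_length_m + b.core_length_m) / 2.0
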