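import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import otternet as ot
from otternet.behavior import (FecalDeposit, choose_bias, deposit_feces,
                               end_of_hour_update, traverse)
from otternet.errors import ParameterError


@pytest.fixture
def params():
    return ot.BehaviorParams()


def make_otter(position, sex="male", satiated=False, heading=1,
               home_center=None, core_length_m=None):
    return ot.OtterState(id=0, sex=sex, activity="active", hours_in_state=0,
                         hours_since_defecation=0, satiated=satiated,
                         position=position, heading=heading,
                         home_center=home_center, core_length_m=core_length_m)


class TestSwitchProbability:
    def test_half_at_mean_duration(self, params):
        assert ot.switch_state_probability("active", 1.433, False,
                                           params) == pytest.approx(0.5)

    def test_satiation_doubles_active_hazard(self, params):
        assert ot.switch_state_probability("active", 1.433, True,
                                           params) == pytest.approx(1.0)

    def test_satiation_halves_wake_hazard(self, params):
        assert ot.switch_state_probability("inactive", 11.692, True,
                                           params) == pytest.approx(0.25)

    @settings(derandomize=True, max_examples=50)
    @given(h=st.floats(0, 50), sat=st.booleans(),
           state=st.sampled_from(["active", "inactive"]))
    def test_always_a_probability(self, h, sat, state):
        q = ot.switch_state_probability(state, h, sat, ot.BehaviorParams())
        assert 0.0 <= q <= 1.0


class TestDefecationProbability:
    def test_half_at_mean_gap(self, params):
        assert ot.defecation_probability(4.865, False,
                                         params) == pytest.approx(0.5)

    def test_satiation_scaler(self, params):
        assert ot.defecation_probability(4.865, True,
                                         params) == pytest.approx(1.0)

    def test_forced_after_nine_hours(self, params):
        assert ot.defecation_probability(9.0, False, params) == 1.0
        assert ot.defecation_probability(9.0, True, params) == 1.0

    @settings(derandomize=True, max_examples=50)
    @given(h=st.floats(0, 20),
           scaler=st.floats(1.0, 4.0))
    def test_monotone_in_scaler(self, h, scaler):
        import dataclasses
        base = ot.BehaviorParams()
        lo = ot.defecation_probability(h, True, base)
        hi = ot.defecation_probability(
            h, True, dataclasses.replace(
                base, satiation_defecation_scaler=max(
                    scaler, base.satiation_defecation_scaler)))
        assert hi >= lo - 1e-12


class TestScentDetection:
    def test_fresh_at_zero_distance(self, params):
        assert ot.scent_detection_probability(0, 0, params) == 1.0

    def test_distance_decay(self, params):
        assert ot.scent_detection_probability(1000, 0, params) == \
            pytest.approx(math.exp(-3.0))

    def test_age_decay(self, params):
        assert ot.scent_detection_probability(0, 24, params) == \
            pytest.approx(math.exp(-2.4))

    def test_hard_zero_beyond_memory(self, params):
        assert ot.scent_detection_probability(1000.1, 0, params) == 0.0


class TestMovementDraw:
    def test_degenerate_sd(self):
        p = ot.BehaviorParams(move_sd_m=0.0)
        assert ot.draw_movement_distance(p, np.random.default_rng(0)) == 941.0

    def test_clamped_nonnegative_and_censored_mean(self, params):
        rng = np.random.default_rng(1)
        draws = np.array([ot.draw_movement_distance(params, rng)
                          for _ in range(100_000)])
        assert (draws >= 0).all()
        mu, sd = params.move_mean_m, params.move_sd_m
        z = mu / sd
        from scipy.stats import norm
        expected = mu * norm.cdf(z) + sd * norm.pdf(z)
        se = draws.std(ddof=1) / math.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 4 * se


class TestChooseBias:
    def test_female_beyond_core_heads_home(self, params):
        net, _, _ = ot.toy_line_world(1000, latrine_ids=[500])
        # 4-km core centred at 500; otter at 900 is 2 km past the edge
        o = make_otter(900, sex="female", home_center=500,
                       core_length_m=4000.0)
        rng = ot.SubStream(1, 0, 0)
        assert choose_bias(o, net, {}, params, rng, hour=5) == 500

    def test_no_cues_no_bias(self, params):
        net, _, _ = ot.toy_line_world(200, latrine_ids=[50])
        o = make_otter(150)
        assert choose_bias(o, net, {}, params, ot.SubStream(1, 0, 0),
                           hour=5) is None

    def test_satiated_targets_best_latrine(self, params):
        net, _, _ = ot.toy_line_world(200)
        net.mep[100 + 80] = 0.9
        net.mep[100 + 10] = 0.7
        o = make_otter(100, satiated=True)
        assert choose_bias(o, net, {}, params, ot.SubStream(1, 0, 0),
                           hour=5) == 180

    def test_olfaction_prefers_nearest_detected(self):
        # make detection near-certain so both trials succeed
        p = ot.BehaviorParams(scent_dist_rate=-1e-9, desiccation_rate=1e-9)
        net, _, _ = ot.toy_line_world(400, latrine_ids=[120, 170])
        o = make_otter(100)
        deposits = {120: 4, 170: 4}   # committed the hour before
        got = choose_bias(o, net, deposits, p, ot.SubStream(1, 0, 0), hour=5)
        assert got == 120   # 200 m beats 700 m


class TestTraverse:
    def test_zero_budget(self, params):
        net, _, _ = ot.toy_line_world(100)
        o = make_otter(50)
        pos, enc, path = traverse(o, net, set(), 0.0, None, params)
        assert pos == 50 and not enc and path == [50]

    def test_stops_within_visual_range_of_school(self, params):
        net, _, _ = ot.toy_line_world(200)
        o = make_otter(50, heading=1)
        pos, enc, _ = traverse(o, net, {80}, 500.0, None, params)
        assert enc
        assert ot.network_distance(net, pos, 80) <= params.visual_m
        # first point within 50 m of the school is 10 points past 50
        assert pos == 75

    def test_bias_overshoot_suppressed(self, params):
        net, _, _ = ot.toy_line_world(200)
        o = make_otter(50, heading=1)
        pos, enc, path = traverse(o, net, set(), 500.0, 70, params)
        assert pos == 70 and not enc
        assert path == list(range(50, 71))

    def test_never_leaves_network(self, params):
        net, _, _ = ot.toy_line_world(30)
        o = make_otter(25, heading=1)
        pos, _, path = traverse(o, net, set(), 2000.0, None, params)
        assert all(0 <= q < 30 for q in path)


class TestDeposition:
    def test_deposit_at_best_latrine(self, params):
        net, _, _ = ot.toy_line_world(300, latrine_ids=[140])
        o = make_otter(100)
        deposits = []
        dep = deposit_feces(o, net, params, hour=7, deposits=deposits)
        assert dep.point == 140 and dep.hour == 7

    def test_fallback_to_current_point(self, params):
        net, _, _ = ot.toy_line_world(300)   # no latrines at all
        o = make_otter(100)
        dep = deposit_feces(o, net, params, hour=7, deposits=[])
        assert dep.point == 100

    def test_one_deposit_per_event(self, params):
        net, _, _ = ot.toy_line_world(300, latrine_ids=[140])
        o = make_otter(100)
        deposits = []
        deposit_feces(o, net, params, 1, deposits)
        deposit_feces(o, net, params, 2, deposits)
        assert len(deposits) == 2
        assert [d.id for d in deposits] == [0, 1]


class TestEndOfHour:
    def test_encounter_sets_satiation(self):
        o = make_otter(0)
        end_of_hour_update(o, encountered=True, defecated=False,
                           switched=False)
        assert o.satiated and o.encounters == 1
        assert o.hours_in_state == 1 and o.hours_since_defecation == 1

    def test_defecation_voids_pelagic_meal(self):
        o = make_otter(0, satiated=True)
        end_of_hour_update(o, encountered=False, defecated=True,
                           switched=False)
        assert not o.satiated
        assert o.hours_since_defecation == 0

    def test_idle_hour_only_advances_clocks(self):
        o = make_otter(0)
        o.activity = "inactive"
        end_of_hour_update(o, encountered=False, defecated=False,
                           switched=False)
        assert o.hours_in_state == 1 and o.hours_since_defecation == 1
        assert not o.satiated and o.encounters == 0
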