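import numpy as np
import pandas as pd
import pytest

import otternet as ot
from otternet import metrics as M
from otternet.engine import ReplicateLog
from otternet.errors import ParameterError


def stub_log(net, pos_log, state_log=None, is_male=None, dep_point=(),
             dep_pelagic=(), defecations=None, n_hours=None):
    """Hand-built log for metric oracles."""
    pos_log = np.asarray(pos_log, dtype=np.int32)
    n, H = pos_log.shape
    if n_hours is None:
        n_hours = H
    if state_log is None:
        state_log = np.ones((n, H), dtype=np.uint8)
    if is_male is None:
        is_male = np.ones(n, dtype=bool)
    dep_point = np.asarray(dep_point, dtype=np.int32)
    k = len(dep_point)
    dep_pelagic = (np.asarray(dep_pelagic, dtype=np.uint8) if len(dep_pelagic)
                   else np.zeros(k, dtype=np.uint8))
    if defecations is None:
        defecations = np.zeros(n, dtype=np.int64)
        defecations[0] = k
    z = lambda: np.zeros(n, dtype=np.int64)
    return ReplicateLog(
        net=net, scenario=ot.get_scenario("School_100%"), seed=0,
        n_hours=n_hours, is_male=np.asarray(is_male, dtype=bool),
        in_study_area=np.ones(n, dtype=bool),
        state_log=np.asarray(state_log, dtype=np.uint8), pos_log=pos_log,
        sat_log=np.zeros((n, H), dtype=np.uint8),
        dep_otter=np.zeros(k, dtype=np.int32), dep_point=dep_point,
        dep_hour=np.zeros(k, dtype=np.int32), dep_pelagic=dep_pelagic,
        school_counts=np.zeros(H, dtype=np.int32),
        school_points=np.full((H, 1), -1, dtype=np.int32),
        encounters=z(), defecations=np.asarray(defecations, dtype=np.int64),
        active_hours=np.asarray(state_log, dtype=np.int64).sum(axis=1),
        demersal_hours=z(), grouped_hours=z(), mixed_hours=z(),
        n_groups_hour=np.zeros(H, dtype=np.int32),
        group_accum=np.array([0, 0, 1 << 30, 0], dtype=np.int64),
        meta={"group_proximity_m": None})


@pytest.fixture(scope="module")
def line_net():
    net, _, _ = ot.toy_line_world(2000)
    return net


class TestDefecationRate:
    def test_division_oracle(self, line_net):
        log = stub_log(line_net, np.zeros((1, 10), dtype=int),
                       dep_point=[0] * 223, n_hours=2232)
        assert M.defecation_rate(log) == pytest.approx(223 / 2232)

    def test_zero_deposits(self, line_net):
        log = stub_log(line_net, np.zeros((1, 10), dtype=int))
        assert M.defecation_rate(log) == 0.0

    def test_rate_never_exceeds_one(self, toy_log):
        rates = toy_log.defecations / toy_log.n_hours
        assert (rates <= 1.0).all()


class TestFecesPerDay:
    def test_arithmetic(self, line_net):
        log = stub_log(line_net, np.zeros((1, 2232), dtype=int),
                       dep_point=[0] * 28644)
        m, lo, hi = M.mean_feces_per_day([log, log])
        assert m == pytest.approx(28644 / 93.0) == pytest.approx(308.0)
        assert lo == hi == pytest.approx(m)   # identical replicates


class TestGroups:
    def test_pair_within_proximity(self, line_net):
        log = stub_log(line_net, [[10], [15]])   # 50 m apart
        groups = M.detect_groups(log, 0, 100.0)
        assert groups == [frozenset({0, 1})]

    def test_chain_is_one_group(self, line_net):
        log = stub_log(line_net, [[0], [9], [18]])  # 0 / 90 / 180 m
        groups = M.detect_groups(log, 0, 100.0)
        assert groups == [frozenset({0, 1, 2})]

    def test_solitary_otters_form_no_groups(self, line_net):
        log = stub_log(line_net, [[0], [500], [1000]])
        assert M.detect_groups(log, 0, 100.0) == []

    def test_inactive_otters_excluded(self, line_net):
        log = stub_log(line_net, [[10], [15]],
                       state_log=[[1], [0]])
        assert M.detect_groups(log, 0, 100.0) == []

    def test_minimum_group_size_is_two(self, toy_log):
        for h in range(toy_log.n_hours):
            for g in M.detect_groups(toy_log, h):
                assert len(g) >= 2

    def test_pinned_otters_grouped_all_the_time(self, line_net):
        pos = np.full((3, 4), 7, dtype=int)
        log = stub_log(line_net, pos, is_male=[True, True, False])
        gm = M.group_metrics([log], proximity_m=100.0)
        assert gm.loc[0, "pct_time_in_group_male"] == 100.0
        assert gm.loc[0, "pct_time_in_group_female"] == 100.0
        assert gm.loc[0, "pct_mixed_male"] == 100.0
        assert gm.loc[0, "mean_group_size"] == 3.0
        assert gm.loc[0, "min_group_size"] == 3

    def test_kernel_tallies_match_recount(self, toy_log):
        slow = M.group_metrics([toy_log], proximity_m=50.0)
        slow2 = M.group_metrics([toy_log], proximity_m=50.0)
        pd.testing.assert_frame_equal(slow, slow2)
        fast = M.group_metrics([toy_log])   # kernel tallies at 100 m
        recount = M.group_metrics([toy_log], proximity_m=100.0001)
        for col in fast.columns:
            a, b = fast.loc[0, col], recount.loc[0, col]
            assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestPelagicShare:
    def test_division(self, line_net):
        log = stub_log(line_net, np.zeros((1, 5), dtype=int),
                       dep_point=[0] * 1000,
                       dep_pelagic=[1] * 359 + [0] * 641)
        assert M.pct_pelagic_feces(log) == pytest.approx(35.9)

    def test_all_pelagic(self, line_net):
        log = stub_log(line_net, np.zeros((1, 5), dtype=int),
                       dep_point=[0, 1], dep_pelagic=[1, 1])
        assert M.pct_pelagic_feces(log) == 100.0

    def test_no_deposits_is_an_error(self, line_net):
        log = stub_log(line_net, np.zeros((1, 5), dtype=int))
        with pytest.raises(ParameterError):
            M.pct_pelagic_feces(log)


class TestCoreRange:
    def test_uniform_occupancy_half_mass(self, line_net):
        # uniform use of a 10-km stretch -> 50% core of about 5 km
        pos = np.tile(np.arange(500, 1500), 3)[None, :]
        log = stub_log(line_net, pos)
        got = M.core_range_length(log, 0, quantile=0.5, bandwidth_m=300.0)
        assert got == pytest.approx(5.0, rel=0.08)

    def test_sedentary_otter_kernel_support(self, line_net):
        log = stub_log(line_net, np.full((1, 100), 1000, dtype=int))
        got = M.core_range_length(log, 0, quantile=0.5, bandwidth_m=300.0)
        assert got < 0.8   # well under the 2x3-sigma kernel support

    def test_females_smaller_than_males(self, toy_log):
        # females are tethered to exclusive cores, males roam freely
        f = [M.core_range_length(toy_log, int(i))
             for i in np.flatnonzero(~toy_log.is_male)]
        m = [M.core_range_length(toy_log, int(i))
             for i in np.flatnonzero(toy_log.is_male)]
        if f and m:
            assert np.mean(f) <= np.mean(m) * 1.5


class TestWindows:
    def test_window_sum(self, line_net):
        log_points = [0, 1, 2, 3, 4] * 10
        w = M.window_counts(np.array(log_points), line_net)
        assert w.loc[0, "count"] == 50
        assert w["count"].sum() == 50

    def test_empty(self, line_net):
        w = M.window_counts(np.array([], dtype=int), line_net)
        assert (w["count"] == 0).all()

    def test_partition_conserves_total(self, toy_log):
        w = M.window_counts(toy_log.dep_point, toy_log.net)
        assert w["count"].sum() == toy_log.n_deposits

    def test_partition_with_corridors(self, small_synthetic_net):
        net = small_synthetic_net
        rng = np.random.default_rng(0)
        pts = rng.integers(0, net.n_points, size=5000)
        w = M.window_counts(pts, net)
        assert w["count"].sum() == 5000
        coast_windows = w[w["is_coast"]]
        assert not net.on_virtual_line[coast_windows["start_id"]].any()


class TestHotspots:
    @pytest.mark.parametrize("total,cls", [
        (151, "hotspot"), (200, "hotspot"), (150, "intermediate"),
        (50, "intermediate"), (49, "background"), (0, "background")])
    def test_classes(self, total, cls):
        assert M.hotspot_classify(total) == cls

    def test_proportions_sum_to_one(self, toy_log):
        w = M.window_counts(toy_log.dep_point, toy_log.net)
        props = M.hotspot_proportions(w)
        assert sum(props.values()) == pytest.approx(1.0)


class TestNitrogen:
    def test_published_conversions(self):
        assert M.annual_nitrogen_kg(308.0) == pytest.approx(578.96, abs=0.01)
        assert M.annual_nitrogen_kg(391.5) == pytest.approx(735.92, abs=0.01)
        assert M.annual_nitrogen_kg(0.0) == 0.0


class TestSummary:
    def test_summary_contains_core_metrics(self, toy_log):
        s = ot.scenario_summary([toy_log]).set_index("metric")
        for name in ("mean_feces_per_day", "pct_pelagic_feces",
                     "defecation_rate", "n_groups", "annual_N_kg",
                     "prop_windows_hotspot"):
            assert name in s.index
        assert (s.loc["mean_feces_per_day", "mean"]
                == pytest.approx(toy_log.n_deposits
                                 / (toy_log.n_hours / 24.0)))
        fin = s.dropna()
        assert (fin["ci_lo"] <= fin["mean"] + 1e-12).all()
        assert (fin["ci_hi"] >= fin["mean"] - 1e-12).all()
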