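"""Replicate orchestration: the hourly scheduler over all otters and schools.

The season runs hourly from May 15 00:00 to Aug 16 00:00 (93 days, 2,232
steps).  Each hour: (1) the school field is refreshed; (2) every otter, in
id order but on its own deterministic random substream, evaluates a state
switch and - if active - chooses a movement bias, draws a search distance,
traverses the network, resolves any fish-school encounter and evaluates
defecation; (3) clocks advance and the hour's deposits become visible to
olfaction from the next hour on.  Because agents interact only through the
previous hour's deposit field and the shared school field, trajectories
are invariant to the within-hour update order, and sociality is a genuine
emergent property rather than a programmed attraction rule.

Randomness
----------
Each replicate derives three independent streams from its seed (numpy
``SeedSequence``): population initialization, the school schedule, and the
behavioural kernel.  The kernel uses a counter-based splitmix64 generator
keyed by ``(replicate seed, otter id, hour)``, so every otter-hour has its
own reproducible substream.  Two interchangeable engines consume these
streams: a compiled (numba) kernel used for production runs and a readable
pure-Python reference (:func:`run_hour`); they are draw-for-draw identical
and the test suite asserts bit-equal logs on small worlds.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import hashlib
import json
import math

import numpy as np
import pandas as pd
from numba import njit

from .errors import ConfigurationError, ParameterError
from .landscape import LandscapeNetwork
from .population import InitParams, OtterState, initialize_population
from .behavior import (BehaviorParams, FecalDeposit, choose_bias,
                       defecation_probability, deposit_feces,
                       switch_state_probability, traverse)
from .fish import ScenarioConfig, build_school_schedule

# ----------------------------------------------------------------------
# Counter-based RNG (splitmix64), Python twin
# ----------------------------------------------------------------------

_MASK = (1 << 64) - 1
_C1 = 0x9E3779B97F4A7C15
_C2 = 0xBF58476D1CE4E5B9
_C3 = 0x94D049BB133111EB


def _fmix64(z: int) -> int:
    z &= _MASK
    z ^= z >> 30
    z = (z * _C2) & _MASK
    z ^= z >> 27
    z = (z * _C3) & _MASK
    return z ^ (z >> 31)


def stream_key(seed: int, otter: int, hour: int) -> int:
    """Initial splitmix64 state for one otter-hour substream."""
    return _fmix64((seed * _C1 + (otter + 1) * _C2 + (hour + 1) * _C3)
                   & _MASK)


class SubStream:
    """Minimal splitmix64 stream; mirrors the compiled kernel exactly."""

    __slots__ = ("state",)

    def __init__(self, seed: int, otter: int, hour: int):
        self.state = stream_key(seed, otter, hour)

    def random(self) -> float:
        self.state = (self.state + _C1) & _MASK
        return (_fmix64(self.state) >> 11) * 2.0 ** -53

    def normal(self, mean: float, sd: float) -> float:
        # Box-Muller; one pair of uniforms per draw, cosine branch only
        u1 = 1.0 - self.random()
        u2 = self.random()
        z = math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)
        return mean + sd * z


# ----------------------------------------------------------------------
# Compiled kernel
# ----------------------------------------------------------------------

_U64 = np.uint64
_K1 = _U64(_C1)
_K2 = _U64(_C2)
_K3 = _U64(_C3)


@njit(cache=True, inline="always")
def _nb_fmix64(z):
    z = np.uint64(z)
    z = z ^ (z >> _U64(30))
    z = z * _K2
    z = z ^ (z >> _U64(27))
    z = z * _K3
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _nb_stream_key(seed, otter, hour):
    return _nb_fmix64(np.uint64(seed) * _K1 + _U64(otter + 1) * _K2
                      + _U64(hour + 1) * _K3)


@njit(cache=True, inline="always")
def _nb_next_u01(state):
    state = np.uint64(state) + _K1
    x = _nb_fmix64(state)
    return state, np.float64(x >> _U64(11)) * (2.0 ** -53)


@njit(cache=True, inline="always")
def _nb_phi(x):
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@njit(cache=True)
def _nb_bfs(indptr, nbr, origin, max_hops, stamp_arr, stamp, dist, parent,
            queue, target):
    """Deterministic FIFO BFS (ascending-id neighbour order).

    Fills hop distances and parents for visited points; ``queue[:nv]`` is
    the visited list in discovery order.  Stops expanding at ``max_hops``
    or as soon as ``target`` (if >= 0) is discovered.
    """
    stamp_arr[origin] = stamp
    dist[origin] = 0
    parent[origin] = -1
    queue[0] = origin
    nv = 1
    head = 0
    while head < nv:
        u = queue[head]
        head += 1
        du = dist[u]
        if du >= max_hops:
            continue
        for k in range(indptr[u], indptr[u + 1]):
            v = nbr[k]
            if stamp_arr[v] != stamp:
                stamp_arr[v] = stamp
                dist[v] = du + 1
                parent[v] = u
                queue[nv] = v
                nv += 1
                if v == target:
                    return nv
    return nv


@njit(cache=True)
def _nb_best_latrine(queue, nv, is_latrine, mep, dist):
    """Highest-MEP latrine among visited points; ties by hop distance then
    id.  Returns -1 when none."""
    best = -1
    best_mep = -1.0
    best_d = 1 << 30
    for k in range(nv):
        pt = queue[k]
        if not is_latrine[pt]:
            continue
        m = mep[pt]
        d = dist[pt]
        if (m > best_mep
                or (m == best_mep and (d < best_d
                                       or (d == best_d and pt < best)))):
            best = pt
            best_mep = m
            best_d = d
    return best


@njit(cache=True)
def _nb_crw_step(indptr, nbr, coords, cur, prev, heading):
    lo = indptr[cur]
    hi = indptr[cur + 1]
    if prev < 0:
        # no history: use the +/-1 coastline ordering convention
        for k in range(lo, hi):
            v = nbr[k]
            if (v - cur) * heading > 0:
                return v
        return nbr[lo]
    n_opt = 0
    only = -1
    for k in range(lo, hi):
        if nbr[k] != prev:
            n_opt += 1
            only = nbr[k]
    if n_opt == 0:
        return prev          # dead end: reverse
    if n_opt == 1:
        return only
    hx = coords[cur, 0] - coords[prev, 0]
    hy = coords[cur, 1] - coords[prev, 1]
    hn = math.hypot(hx, hy)
    best = -1
    best_cos = -2.0
    for k in range(lo, hi):
        v = nbr[k]
        if v == prev:
            continue
        ex = coords[v, 0] - coords[cur, 0]
        ey = coords[v, 1] - coords[cur, 1]
        en = math.hypot(ex, ey)
        c = (hx * ex + hy * ey) / (hn * en) if hn > 0 and en > 0 else 0.0
        # ascending-id iteration: first hit wins ties (lowest id)
        if c > best_cos:
            best = v
            best_cos = c
    return best


@njit(cache=True)
def _nb_union_find(parent_uf, i):
    root = i
    while parent_uf[root] != root:
        root = parent_uf[root]
    while parent_uf[i] != root:
        nxt = parent_uf[i]
        parent_uf[i] = root
        i = nxt
    return root


# parameter vector layout for the kernel
_P_MOVE_MU, _P_MOVE_SD, _P_DEF_MU, _P_DEF_SD, _P_ACT_MU, _P_ACT_SD, \
    _P_INACT_MU, _P_INACT_SD, _P_SCENT, _P_DESIC, _P_ACT_SCALE, \
    _P_DEF_SCALE, _P_FORCED = range(13)


@njit(cache=True)
def _run_kernel(indptr, nbr, coords, mep, is_latrine,
                school_counts, school_points,
                vis_hops, mem_hops, prox_hops,
                is_male, activity, hours_state, hours_defec,
                position, prev_point, heading, home_center, core_half_m,
                params, seed, n_hours,
                state_log, pos_log, sat_log,
                dep_otter, dep_point, dep_hour, dep_pelagic,
                encounters, defecations, active_hours, demersal_hours,
                grouped_hours, mixed_hours, n_groups_hour, group_accum):
    n_points = mep.shape[0]
    n_otters = is_male.shape[0]

    stamp_arr = np.full(n_points, -1, dtype=np.int64)
    dist = np.zeros(n_points, dtype=np.int32)
    parent = np.zeros(n_points, dtype=np.int32)
    queue = np.zeros(n_points, dtype=np.int32)
    stamp = 0

    school_stamp = np.full(n_points, -1, dtype=np.int64)
    sch_dist = np.zeros(n_points, dtype=np.int32)
    sch_queue = np.zeros(n_points, dtype=np.int32)

    last_dep_hour = np.full(n_points, -1, dtype=np.int64)
    satiated = np.zeros(n_otters, dtype=np.uint8)

    path_buf = np.zeros(n_points, dtype=np.int32)
    cand_pt = np.zeros(n_points, dtype=np.int32)
    cand_d = np.zeros(n_points, dtype=np.int32)

    occ_head = np.full(n_points, -1, dtype=np.int32)
    occ_next = np.full(n_otters, -1, dtype=np.int32)
    occ_stamp = np.full(n_points, -1, dtype=np.int64)
    uf = np.zeros(n_otters, dtype=np.int32)
    comp_size = np.zeros(n_otters, dtype=np.int32)
    comp_male = np.zeros(n_otters, dtype=np.int32)
    comp_female = np.zeros(n_otters, dtype=np.int32)

    n_dep = 0
    # group_accum: [0]=total members, [1]=total groups, [2]=min size,
    # [3]=max size
    group_accum[2] = 1 << 30

    for h in range(n_hours):
        # --- multi-source BFS: points within visual range of any school ---
        nsch = school_counts[h]
        if nsch > 0:
            head = 0
            nv = 0
            for s in range(nsch):
                sp = school_points[h, s]
                if school_stamp[sp] != h:
                    school_stamp[sp] = h
                    sch_dist[sp] = 0
                    sch_queue[nv] = sp
                    nv += 1
            while head < nv:
                u = sch_queue[head]
                head += 1
                du = sch_dist[u]
                if du >= vis_hops:
                    continue
                for k in range(indptr[u], indptr[u + 1]):
                    v = nbr[k]
                    if school_stamp[v] != h:
                        school_stamp[v] = h
                        sch_dist[v] = du + 1
                        sch_queue[nv] = v
                        nv += 1

        dep_start = n_dep

        # --- per-otter decisions ---
        for i in range(n_otters):
            state = _nb_stream_key(seed, i, h)
            active = activity[i] == 1
            sat = satiated[i] == 1

            # state switch
            state, u = _nb_next_u01(state)
            if active:
                q = _nb_phi((hours_state[i] - params[_P_ACT_MU])
                            / params[_P_ACT_SD])
                if sat:
                    q = min(1.0, q * params[_P_ACT_SCALE])
            else:
                q = _nb_phi((hours_state[i] - params[_P_INACT_MU])
                            / params[_P_INACT_SD])
                if sat:
                    q = q / params[_P_ACT_SCALE]
            switched = u < q
            if switched:
                active = not active

            encountered = False
            defecated = False

            if active:
                pos = position[i]
                bias = -1
                plan_len = -1   # -1: no plan (CRW); >=0: follow path_buf

                # (1) female beyond her core edge heads home
                if (not is_male[i]) and home_center[i] >= 0:
                    half_hops = np.int32(core_half_m[i] // 10.0)
                    stamp += 1
                    _nb_bfs(indptr, nbr, pos, half_hops, stamp_arr, stamp,
                            dist, parent, queue, home_center[i])
                    if stamp_arr[home_center[i]] != stamp:
                        bias = home_center[i]
                        stamp += 1
                        _nb_bfs(indptr, nbr, pos, np.int32(n_points),
                                stamp_arr, stamp, dist, parent, queue, bias)
                        plan_len = _build_path(parent, path_buf, pos, bias)

                if bias < 0:
                    stamp += 1
                    nv = _nb_bfs(indptr, nbr, pos, mem_hops, stamp_arr,
                                 stamp, dist, parent, queue, np.int32(-1))
                    # (2) satiated: nearest highest-quality latrine
                    if sat:
                        best = _nb_best_latrine(queue, nv, is_latrine, mep,
                                                dist)
                        if best >= 0:
                            bias = best
                            plan_len = _build_path(parent, path_buf, pos,
                                                   bias)
                    # (3) olfaction over latrines holding committed deposits
                    if bias < 0:
                        ncand = 0
                        for k in range(nv):
                            pt = queue[k]
                            if pt == pos or not is_latrine[pt]:
                                continue
                            if last_dep_hour[pt] < 0 or last_dep_hour[pt] >= h:
                                continue
                            # insertion sort by id for a stable draw order
                            j = ncand
                            while j > 0 and cand_pt[j - 1] > pt:
                                cand_pt[j] = cand_pt[j - 1]
                                cand_d[j] = cand_d[j - 1]
                                j -= 1
                            cand_pt[j] = pt
                            cand_d[j] = dist[pt]
                            ncand += 1
                        best_d = 1 << 30
                        best_mep = -1.0
                        best_pt = -1
                        for c in range(ncand):
                            pt = cand_pt[c]
                            d_m = cand_d[c] * 10.0
                            age = np.float64(h - last_dep_hour[pt])
                            prob = math.exp(params[_P_SCENT] * d_m) * \
                                math.exp(-params[_P_DESIC] * age)
                            state, u = _nb_next_u01(state)
                            if u < prob:
                                d = cand_d[c]
                                m = mep[pt]
                                if (d < best_d
                                        or (d == best_d
                                            and (m > best_mep
                                                 or (m == best_mep
                                                     and pt < best_pt)))):
                                    best_d = d
                                    best_mep = m
                                    best_pt = pt
                        if best_pt >= 0:
                            bias = best_pt
                            plan_len = _build_path(parent, path_buf, pos,
                                                   bias)

                # movement draw (Box-Muller pair), clamped at zero
                state, u1 = _nb_next_u01(state)
                state, u2 = _nb_next_u01(state)
                z = math.sqrt(-2.0 * math.log(1.0 - u1)) * \
                    math.cos(2.0 * math.pi * u2)
                budget = params[_P_MOVE_MU] + params[_P_MOVE_SD] * z
                if budget < 0.0:
                    budget = 0.0
                steps = np.int64(budget // 10.0)

                prev = prev_point[i]
                if nsch > 0 and school_stamp[pos] == h:
                    encountered = True
                else:
                    for st in range(steps):
                        if plan_len >= 0:
                            if st >= plan_len:
                                break      # arrived at the bias target
                            nxt = path_buf[st]
                        else:
                            nxt = _nb_crw_step(indptr, nbr, coords, pos,
                                               prev, heading[i])
                        prev = pos
                        pos = nxt
                        if nsch > 0 and school_stamp[pos] == h:
                            encountered = True
                            break
                if pos != position[i]:
                    heading[i] = 1 if pos > prev else -1
                    prev_point[i] = prev
                    position[i] = pos

                if encountered:
                    sat = True
                    encounters[i] += 1
                else:
                    demersal_hours[i] += 1

                # defecation
                state, u = _nb_next_u01(state)
                if hours_defec[i] >= params[_P_FORCED]:
                    q = 1.0
                else:
                    q = _nb_phi((hours_defec[i] - params[_P_DEF_MU])
                                / params[_P_DEF_SD])
                    if sat:
                        q = min(1.0, q * params[_P_DEF_SCALE])
                defecated = u < q
                if defecated:
                    stamp += 1
                    nv = _nb_bfs(indptr, nbr, pos, mem_hops, stamp_arr,
                                 stamp, dist, parent, queue, np.int32(-1))
                    site = _nb_best_latrine(queue, nv, is_latrine, mep, dist)
                    if site < 0:
                        site = pos
                    dep_otter[n_dep] = i
                    dep_point[n_dep] = site
                    dep_hour[n_dep] = h
                    dep_pelagic[n_dep] = 1 if sat else 0
                    n_dep += 1
                    defecations[i] += 1
                    if sat:
                        sat = False
                active_hours[i] += 1

            # end-of-hour clocks
            if defecated:
                hours_defec[i] = 0
            else:
                hours_defec[i] += 1
            if switched:
                hours_state[i] = 0
            else:
                hours_state[i] += 1
            activity[i] = 1 if active else 0
            satiated[i] = 1 if sat else 0
            state_log[i, h] = activity[i]
            pos_log[i, h] = position[i]
            sat_log[i, h] = satiated[i]

        # commit this hour's deposits (visible from next hour on)
        for d in range(dep_start, n_dep):
            last_dep_hour[dep_point[d]] = h

        # --- social groups among active otters ---
        n_active = 0
        for i in range(n_otters):
            if activity[i] == 1:
                n_active += 1
                uf[i] = i
                p = position[i]
                if occ_stamp[p] != h:
                    occ_stamp[p] = h
                    occ_head[p] = i
                    occ_next[i] = -1
                else:
                    occ_next[i] = occ_head[p]
                    occ_head[p] = i
        if n_active >= 2:
            for i in range(n_otters):
                if activity[i] != 1:
                    continue
                stamp += 1
                nv = _nb_bfs(indptr, nbr, position[i], prox_hops, stamp_arr,
                             stamp, dist, parent, queue, np.int32(-1))
                for k in range(nv):
                    pt = queue[k]
                    if occ_stamp[pt] == h:
                        j = occ_head[pt]
                        while j >= 0:
                            if j != i and activity[j] == 1:
                                ri = _nb_union_find(uf, i)
                                rj = _nb_union_find(uf, j)
                                if ri != rj:
                                    uf[rj] = ri
                            j = occ_next[j]
            for i in range(n_otters):
                comp_size[i] = 0
                comp_male[i] = 0
                comp_female[i] = 0
            for i in range(n_otters):
                if activity[i] != 1:
                    continue
                r = _nb_union_find(uf, i)
                comp_size[r] += 1
                if is_male[i]:
                    comp_male[r] += 1
                else:
                    comp_female[r] += 1
            ng = 0
            for r in range(n_otters):
                s = comp_size[r]
                if s >= 2:
                    ng += 1
                    group_accum[0] += s
                    if s < group_accum[2]:
                        group_accum[2] = s
                    if s > group_accum[3]:
                        group_accum[3] = s
            group_accum[1] += ng
            n_groups_hour[h] = ng
            for i in range(n_otters):
                if activity[i] != 1:
                    continue
                r = _nb_union_find(uf, i)
                if comp_size[r] >= 2:
                    grouped_hours[i] += 1
                    if comp_male[r] > 0 and comp_female[r] > 0:
                        mixed_hours[i] += 1

    return n_dep


@njit(cache=True)
def _build_path(parent, path_buf, origin, target):
    """Back-track the BFS tree target -> origin; writes the forward path
    (excluding origin) into ``path_buf`` and returns its length."""
    n = 0
    cur = target
    while cur != origin:
        path_buf[n] = cur
        n += 1
        cur = parent[cur]
    # reverse in place
    for k in range(n // 2):
        tmp = path_buf[k]
        path_buf[k] = path_buf[n - 1 - k]
        path_buf[n - 1 - k] = tmp
    return n


# ----------------------------------------------------------------------
# Logs and drivers
# ----------------------------------------------------------------------

@dataclass
class ReplicateLog:
    """Full per-replicate record: hourly otter states and positions,
    deposits, schools, per-otter tallies and social-group summaries."""

    net: LandscapeNetwork
    scenario: ScenarioConfig
    seed: int
    n_hours: int
    is_male: np.ndarray
    in_study_area: np.ndarray
    state_log: np.ndarray       # (n_otters, n_hours) uint8, 1 = active
    pos_log: np.ndarray         # (n_otters, n_hours) int32
    sat_log: np.ndarray         # (n_otters, n_hours) uint8
    dep_otter: np.ndarray
    dep_point: np.ndarray
    dep_hour: np.ndarray
    dep_pelagic: np.ndarray
    school_counts: np.ndarray
    school_points: np.ndarray
    encounters: np.ndarray
    defecations: np.ndarray
    active_hours: np.ndarray
    demersal_hours: np.ndarray
    grouped_hours: np.ndarray
    mixed_hours: np.ndarray
    n_groups_hour: np.ndarray
    group_accum: np.ndarray     # [members, groups, min size, max size]
    meta: dict

    @property
    def n_otters(self) -> int:
        return len(self.is_male)

    @property
    def n_deposits(self) -> int:
        return len(self.dep_otter)

    @property
    def deposits(self) -> pd.DataFrame:
        return pd.DataFrame({
            "otter_id": self.dep_otter, "point_id": self.dep_point,
            "hour": self.dep_hour, "pelagic": self.dep_pelagic.astype(bool)})

    @property
    def otter_hours(self) -> pd.DataFrame:
        n, H = self.state_log.shape
        return pd.DataFrame({
            "hour": np.repeat(np.arange(H), n),
            "otter_id": np.tile(np.arange(n), H),
            "active": self.state_log.T.ravel().astype(bool),
            "position": self.pos_log.T.ravel(),
            "satiated": self.sat_log.T.ravel().astype(bool)})

    @property
    def schools(self) -> pd.DataFrame:
        rows = []
        for h in range(self.n_hours):
            c = int(self.school_counts[h])
            for s in range(c):
                rows.append((h, s, int(self.school_points[h, s])))
        return pd.DataFrame(rows, columns=["hour", "school_id", "point_id"])

    def deposits_hash(self) -> str:
        m = hashlib.sha256()
        for arr in (self.dep_otter, self.dep_point, self.dep_hour,
                    self.dep_pelagic):
            m.update(np.ascontiguousarray(arr).tobytes())
        return m.hexdigest()


def _config_hash(cfg, init, behav) -> str:
    doc = json.dumps({"scenario": asdict(cfg), "init": asdict(init),
                      "behavior": asdict(behav)}, sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def replicate_seed(base_seed: int, replicate: int) -> int:
    """Documented split of (base_seed, replicate) into a replicate seed."""
    return int(np.random.SeedSequence([int(base_seed), int(replicate)])
               .generate_state(1)[0] & 0x7FFFFFFF)


def _prepare_replicate(net, cfg, init, behav, seed):
    ss = np.random.SeedSequence(int(seed))
    c_init, c_schools, c_kernel = ss.spawn(3)
    rng_init = np.random.default_rng(c_init)
    otters, study_n = initialize_population(net, init, rng_init)
    rng_sch = np.random.default_rng(c_schools)
    season_max, counts, points = build_school_schedule(net, cfg, rng_sch)
    kernel_seed = int(c_kernel.generate_state(1)[0] & 0x7FFFFFFF)
    return otters, study_n, season_max, counts, points, kernel_seed


def run_replicate(net: LandscapeNetwork, cfg: ScenarioConfig,
                  init: InitParams, behav: BehaviorParams, seed: int,
                  group_proximity_m: float = 100.0,
                  n_hours: int | None = None,
                  engine: str = "fast") -> ReplicateLog:
    """Run one full-season replicate; byte-identical for identical inputs."""
    if not net.uniform_10m:
        raise ConfigurationError(
            "the simulation engine requires the standard uniform 10-m "
            "point discretization")
    if n_hours is None:
        n_hours = cfg.season_days * 24
    otters, study_n, season_max, counts, points, kernel_seed = \
        _prepare_replicate(net, cfg, init, behav, seed)
    n = len(otters)

    is_male = np.array([o.sex == "male" for o in otters], dtype=np.uint8)
    in_study = np.array([o.in_study_area for o in otters], dtype=np.uint8)
    activity = np.array([o.activity == "active" for o in otters],
                        dtype=np.uint8)
    hours_state = np.array([o.hours_in_state for o in otters],
                           dtype=np.int64)
    hours_defec = np.array([o.hours_since_defecation for o in otters],
                           dtype=np.int64)
    position = np.array([o.position for o in otters], dtype=np.int32)
    prev_point = np.full(n, -1, dtype=np.int32)
    heading = np.array([o.heading for o in otters], dtype=np.int32)
    home_center = np.array(
        [o.home_center if o.home_center is not None else -1 for o in otters],
        dtype=np.int32)
    core_half = np.array(
        [0.5 * o.core_length_m if o.core_length_m is not None else 0.0
         for o in otters], dtype=np.float64)

    params = np.array([
        behav.move_mean_m, behav.move_sd_m, behav.defec_mean_h,
        behav.defec_sd_h, behav.active_mean_h, behav.active_sd_h,
        behav.inactive_mean_h, behav.inactive_sd_h, behav.scent_dist_rate,
        behav.desiccation_rate, behav.satiation_activity_scaler,
        behav.satiation_defecation_scaler, behav.forced_defecation_h],
        dtype=np.float64)

    state_log = np.zeros((n, n_hours), dtype=np.uint8)
    pos_log = np.zeros((n, n_hours), dtype=np.int32)
    sat_log = np.zeros((n, n_hours), dtype=np.uint8)
    cap = n * n_hours
    dep_otter = np.zeros(cap, dtype=np.int32)
    dep_point = np.zeros(cap, dtype=np.int32)
    dep_hour = np.zeros(cap, dtype=np.int32)
    dep_pelagic = np.zeros(cap, dtype=np.uint8)
    per = lambda: np.zeros(n, dtype=np.int64)
    encounters, defecations = per(), per()
    active_hours, demersal_hours = per(), per()
    grouped_hours, mixed_hours = per(), per()
    n_groups_hour = np.zeros(n_hours, dtype=np.int32)
    group_accum = np.zeros(4, dtype=np.int64)

    indptr, nbr, _ = net.csr_adjacency()

    if engine == "fast":
        n_dep = _run_kernel(
            indptr, nbr.astype(np.int32), net.coords, net.mep,
            net.is_latrine, counts[:n_hours], points,
            np.int32(behav.visual_m // 10.0),
            np.int32(behav.memory_m // 10.0),
            np.int32(group_proximity_m // 10.0),
            is_male, activity, hours_state, hours_defec, position,
            prev_point, heading, home_center, core_half, params,
            _U64(kernel_seed), n_hours,
            state_log, pos_log, sat_log,
            dep_otter, dep_point, dep_hour, dep_pelagic,
            encounters, defecations, active_hours, demersal_hours,
            grouped_hours, mixed_hours, n_groups_hour, group_accum)
    elif engine == "reference":
        world = World(net=net, otters=otters, behav=behav,
                      school_counts=counts[:n_hours], school_points=points,
                      kernel_seed=kernel_seed,
                      group_proximity_m=group_proximity_m)
        for h in range(n_hours):
            run_hour(world, h)
        n_dep = _collect_reference(world, otters, n_hours, state_log,
                                   pos_log, sat_log, dep_otter, dep_point,
                                   dep_hour, dep_pelagic, encounters,
                                   defecations, active_hours,
                                   demersal_hours, grouped_hours,
                                   mixed_hours, n_groups_hour, group_accum)
    else:
        raise ParameterError(f"unknown engine {engine!r}")

    meta = {"seed": int(seed), "kernel_seed": int(kernel_seed),
            "config_hash": _config_hash(cfg, init, behav),
            "scenario": cfg.name, "n_otters": int(n),
            "study_area_n": int(study_n), "season_max_schools":
            int(season_max), "n_hours": int(n_hours),
            "group_proximity_m": float(group_proximity_m)}
    sl = slice(0, n_dep)
    return ReplicateLog(
        net=net, scenario=cfg, seed=int(seed), n_hours=n_hours,
        is_male=is_male.astype(bool), in_study_area=in_study.astype(bool),
        state_log=state_log, pos_log=pos_log, sat_log=sat_log,
        dep_otter=dep_otter[sl].copy(), dep_point=dep_point[sl].copy(),
        dep_hour=dep_hour[sl].copy(), dep_pelagic=dep_pelagic[sl].copy(),
        school_counts=counts[:n_hours], school_points=points,
        encounters=encounters, defecations=defecations,
        active_hours=active_hours, demersal_hours=demersal_hours,
        grouped_hours=grouped_hours, mixed_hours=mixed_hours,
        n_groups_hour=n_groups_hour, group_accum=group_accum, meta=meta)


def run_scenario(net, cfg, init, behav, n_replicates: int, base_seed: int,
                 **kwargs) -> list[ReplicateLog]:
    """Independent replicates seeded by a documented split of
    ``(base_seed, r)``; results are order-insensitive."""
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    return [run_replicate(net, cfg, init, behav,
                          replicate_seed(base_seed, r), **kwargs)
            for r in range(n_replicates)]


# ----------------------------------------------------------------------
# Pure-Python reference engine
# ----------------------------------------------------------------------

@dataclass
class World:
    """Mutable world state for the reference engine."""

    net: LandscapeNetwork
    otters: list
    behav: BehaviorParams
    school_counts: np.ndarray
    school_points: np.ndarray
    kernel_seed: int
    group_proximity_m: float = 100.0

    def __post_init__(self):
        self.deposits: list[FecalDeposit] = []
        self.committed: dict[int, int] = {}   # point -> freshest dep hour
        self.state_rows = []                  # (hour, id, active, pos, sat)
        self.demersal = {o.id: 0 for o in self.otters}
        self.defec_count = {o.id: 0 for o in self.otters}


def run_hour(world: World, hour: int, order=None) -> World:
    """Advance every otter by one hour (reference implementation).

    ``order`` permutes the update sequence; because otters interact only
    through the previous hour's deposit field, any order yields identical
    trajectories (a property the tests exercise).
    """
    net, p = world.net, world.behav
    nsch = int(world.school_counts[hour])
    schools = set(int(x) for x in world.school_points[hour, :nsch])
    new_deposits = []
    if order is None:
        order = range(len(world.otters))
    for idx in order:
        o = world.otters[idx]
        rng = SubStream(world.kernel_seed, o.id, hour)
        state = o.activity
        sat0 = o.satiated
        q = switch_state_probability(state, o.hours_in_state, sat0, p)
        switched = rng.random() < q
        if switched:
            o.activity = "inactive" if state == "active" else "active"
        encountered = False
        defecated = False
        if o.activity == "active":
            bias = choose_bias(o, net, world.committed, p, rng, hour=hour)
            budget = max(0.0, rng.normal(p.move_mean_m, p.move_sd_m))
            _, encountered, _ = traverse(o, net, schools, budget, bias, p)
            if encountered:
                o.satiated = True
            else:
                world.demersal[o.id] += 1
            q = defecation_probability(o.hours_since_defecation,
                                       o.satiated, p)
            defecated = rng.random() < q
            if defecated:
                dep = deposit_feces(o, net, p, hour, world.deposits)
                new_deposits.append(dep)
                world.defec_count[o.id] += 1
                if o.satiated:
                    o.satiated = False
        # clocks
        if defecated:
            o.hours_since_defecation = 0
        else:
            o.hours_since_defecation += 1
        if switched:
            o.hours_in_state = 0
        else:
            o.hours_in_state += 1
        if encountered:
            o.encounters += 1
    for o in world.otters:
        world.state_rows.append((hour, o.id, o.activity == "active",
                                 o.position, o.satiated))
    for dep in new_deposits:
        world.committed[dep.point] = hour
    return world


def _collect_reference(world, otters, n_hours, state_log, pos_log, sat_log,
                       dep_otter, dep_point, dep_hour, dep_pelagic,
                       encounters, defecations, active_hours,
                       demersal_hours, grouped_hours, mixed_hours,
                       n_groups_hour, group_accum):
    for (h, i, act, pos, sat) in world.state_rows:
        state_log[i, h] = 1 if act else 0
        pos_log[i, h] = pos
        sat_log[i, h] = 1 if sat else 0
    for d, dep in enumerate(world.deposits):
        dep_otter[d] = dep.otter_id
        dep_point[d] = dep.point
        dep_hour[d] = dep.hour
        dep_pelagic[d] = 1 if dep.pelagic else 0
    for o in otters:
        encounters[o.id] = o.encounters
        defecations[o.id] = world.defec_count[o.id]
        demersal_hours[o.id] = world.demersal[o.id]
    active_hours[:] = state_log.sum(axis=1)
    group_accum[2] = 1 << 30
    is_male = np.array([o.sex == "male" for o in otters])
    for h in range(n_hours):
        groups = detect_groups_from_arrays(
            world.net, state_log[:, h].astype(bool), pos_log[:, h],
            world.group_proximity_m)
        n_groups_hour[h] = len(groups)
        group_accum[1] += len(groups)
        for g in groups:
            group_accum[0] += len(g)
            group_accum[2] = min(group_accum[2], len(g))
            group_accum[3] = max(group_accum[3], len(g))
            mixed = is_male[list(g)].any() and (~is_male[list(g)]).any()
            for i in g:
                grouped_hours[i] += 1
                if mixed:
                    mixed_hours[i] += 1
    return len(world.deposits)


def detect_groups_from_arrays(net, active_mask, positions, proximity_m):
    """Connected components (size >= 2) of active otters within
    ``proximity_m`` network distance of one another."""
    import networkx as nx
    from .landscape import points_within
    idx = np.flatnonzero(active_mask)
    g = nx.Graph()
    g.add_nodes_from(int(i) for i in idx)
    pos_of = {}
    for i in idx:
        pos_of.setdefault(int(positions[i]), []).append(int(i))
    for i in idx:
        ids, _ = points_within(net, int(positions[i]), proximity_m)
        near = set(int(x) for x in ids)
        for pt, others in pos_of.items():
            if pt in near:
                for j in others:
                    if j != int(i):
                        g.add_edge(int(i), j)
    return [frozenset(c) for c in nx.connected_components(g) if len(c) >= 2]
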