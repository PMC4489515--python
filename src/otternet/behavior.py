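"""Per-hour, per-otter decision rules: state switching, perception,
biased correlated movement, foraging outcome and defecation.

Hazard forms
------------
The probability of leaving the current activity state after ``h`` hours and
the probability of defecating ``h`` hours after the last event are modelled
as normal-CDF hazards ``q = Phi((h - mu) / sigma)`` using the telemetry /
captive-study means and SDs (active 1.433 (1.393) h, inactive 11.692
(8.286) h, defecation gap 4.865 (1.825) h).  A fish-school meal (the
"satiation" state) scales these hazards: an active, satiated otter is twice
as likely to stop foraging, an inactive one half as likely to wake, and a
satiated otter is twice as likely to defecate.  Defecation is forced once
9 h have elapsed, on the assumption the otter has fed on
intertidal-demersal prey in the interim.

Olfactory communication uses a separable exponential kernel: the
probability of detecting a fecal scent mark at network distance ``d`` (m)
and age ``a`` (h) is ``exp(-0.003 d) * exp(-0.1 a)``, zeroed beyond the
1-km memory-perception distance.

These functions are the readable reference implementation; the simulation
engine (:mod:`otternet.engine`) runs a numerically identical compiled
kernel and is cross-checked against this module in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .errors import ParameterError
from .landscape import LandscapeNetwork

#: Standard normal CDF.
def _phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


@dataclass
class BehaviorParams:
    """Run-time behavioural parameters (means/SDs from field estimates)."""

    move_mean_m: float = 941.0
    move_sd_m: float = 1731.0
    defec_mean_h: float = 4.865
    defec_sd_h: float = 1.825
    active_mean_h: float = 1.433
    active_sd_h: float = 1.393
    inactive_mean_h: float = 11.692
    inactive_sd_h: float = 8.286
    scent_dist_rate: float = -0.003   # per metre, < 0
    desiccation_rate: float = 0.1     # per hour, > 0
    visual_m: float = 50.0
    memory_m: float = 1000.0
    satiation_activity_scaler: float = 2.0
    satiation_defecation_scaler: float = 2.0
    forced_defecation_h: float = 9.0

    def __post_init__(self):
        for name in ("move_sd_m", "defec_sd_h", "active_sd_h",
                     "inactive_sd_h"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.satiation_activity_scaler < 1 or \
                self.satiation_defecation_scaler < 1:
            raise ParameterError("satiation scalers must be >= 1")
        if self.visual_m > self.memory_m:
            raise ParameterError("visual_m must be <= memory_m")
        if self.scent_dist_rate >= 0:
            raise ParameterError("scent_dist_rate must be < 0")
        if self.desiccation_rate <= 0:
            raise ParameterError("desiccation_rate must be > 0")


@dataclass
class FecalDeposit:
    """A time-stamped scat record; the unit of nutrient accounting and of
    olfactory communication.  ``pelagic`` flags a deposit voided while the
    otter was satiated on schooling fish."""

    id: int
    otter_id: int
    point: int
    hour: int
    pelagic: bool


# ----------------------------------------------------------------------
# Probability kernels
# ----------------------------------------------------------------------

def switch_state_probability(state: str, hours_in_state: float,
                             satiated: bool, p: BehaviorParams) -> float:
    """Probability of switching activity state this hour."""
    if hours_in_state < 0:
        raise ParameterError("hours_in_state must be >= 0")
    if state == "active":
        q = _phi((hours_in_state - p.active_mean_h) / p.active_sd_h)
        if satiated:
            q = min(1.0, q * p.satiation_activity_scaler)
    elif state == "inactive":
        q = _phi((hours_in_state - p.inactive_mean_h) / p.inactive_sd_h)
        if satiated:
            q = q / p.satiation_activity_scaler
    else:
        raise ParameterError(f"unknown state {state!r}")
    return min(1.0, max(0.0, q))


def defecation_probability(hours_since: float, satiated: bool,
                           p: BehaviorParams) -> float:
    """Probability of a defecation event given the time since the last one.

    Forced to 1 once ``forced_defecation_h`` (default 9 h) have elapsed.
    """
    if hours_since < 0:
        raise ParameterError("hours_since must be >= 0")
    if hours_since >= p.forced_defecation_h:
        return 1.0
    q = _phi((hours_since - p.defec_mean_h) / p.defec_sd_h)
    if satiated:
        q = min(1.0, q * p.satiation_defecation_scaler)
    return q


def scent_detection_probability(distance_m: float, age_h: float,
                                p: BehaviorParams) -> float:
    """Probability of detecting a scat of the given age at the given
    network distance; zero beyond the memory-perception distance."""
    if distance_m < 0 or age_h < 0:
        raise ParameterError("distance and age must be >= 0")
    if distance_m > p.memory_m:
        return 0.0
    return math.exp(p.scent_dist_rate * distance_m) * \
        math.exp(-p.desiccation_rate * age_h)


def draw_movement_distance(p: BehaviorParams, rng) -> float:
    """Hourly search distance: Normal(941, 1731) m with negative draws
    clamped to zero (the otter stays put but remains active)."""
    return max(0.0, rng.normal(p.move_mean_m, p.move_sd_m))


# ----------------------------------------------------------------------
# Perception / movement on the network
# ----------------------------------------------------------------------

def _bfs_within(net: LandscapeNetwork, origin: int, radius_m: float):
    """Hop BFS on a uniform 10-m network: ``{point: (distance_m, parent)}``.

    Neighbour lists are explored in ascending-id order, so the implied
    shortest-path tree (and every tie-break downstream) is deterministic.
    The compiled engine kernel runs the identical algorithm.
    """
    indptr, nbr, _ = net.csr_adjacency()
    max_hops = int(radius_m // 10.0)
    dist = {origin: (0.0, -1)}
    frontier = [origin]
    for hop in range(1, max_hops + 1):
        nxt = []
        for u in frontier:
            for v in nbr[indptr[u]:indptr[u + 1]]:
                v = int(v)
                if v not in dist:
                    dist[v] = (hop * 10.0, u)
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return dist


def choose_bias(otter, net: LandscapeNetwork, deposits, p: BehaviorParams,
                rng, hour: int | None = None):
    """Choose this hour's movement bias target (a point id) or ``None``.

    Priority: (1) a female beyond her core edge heads for her home centre;
    (2) a satiated otter heads for the nearest highest-quality latrine in
    memory range; (3) otherwise one Bernoulli scent-detection trial is run
    for each latrine point in memory range holding a (previous-hour or
    older) deposit, using its freshest deposit, and the nearest success is
    the target (ties: higher MEP, then lower id); (4) no bias - the walk
    continues by pure persistence.

    ``deposits`` maps point id -> most recent deposit hour (committed, i.e.
    laid before the current hour).  ``hour`` is the current hour used for
    scent ageing (age 1 h for a deposit laid the previous hour).
    """
    reach = _bfs_within(net, otter.position, p.memory_m)

    if otter.sex == "female" and otter.home_center is not None:
        half = 0.5 * otter.core_length_m
        d_home = _distance_to(net, otter, half)
        if d_home > half:
            return int(otter.home_center)

    if otter.satiated:
        best = _nearest_best_latrine_bfs(net, reach)
        if best is not None:
            return best

    hour = 0 if hour is None else hour
    successes = []
    for pt in sorted(k for k in reach if k != otter.position):
        if not net.is_latrine[pt]:
            continue
        dep_hour = deposits.get(pt)
        if dep_hour is None or dep_hour >= hour:
            continue
        d, _ = reach[pt]
        prob = scent_detection_probability(d, float(hour - dep_hour), p)
        if rng.random() < prob:
            successes.append((d, -net.mep[pt], pt))
    if successes:
        successes.sort()
        return int(successes[0][2])
    return None


def _distance_to(net, otter, cutoff_half):
    """Network distance from the otter to its home centre, searched out to
    a generous cutoff; returns +inf if farther than the search bound."""
    target = int(otter.home_center)
    reach = _bfs_within(net, otter.position, max(cutoff_half * 2, 20_000.0))
    return reach.get(target, (math.inf, -1))[0]


def _nearest_best_latrine_bfs(net, reach):
    best = None
    for pt, (d, _) in reach.items():
        if not net.is_latrine[pt]:
            continue
        key = (-net.mep[pt], d, pt)
        if best is None or key < best:
            best = key
    return int(best[2]) if best is not None else None


def _next_crw_step(net: LandscapeNetwork, cur: int, prev: int,
                   heading: int) -> int:
    """Persistence step: at degree-2 points continue through; at junctions
    take the edge minimising the turn angle; reverse only at dead ends."""
    indptr, nbr, _ = net.csr_adjacency()
    nbrs = [int(v) for v in nbr[indptr[cur]:indptr[cur + 1]]]
    if prev < 0:
        # no history: fall back on the +/-1 coastline heading convention
        forward = [v for v in nbrs if (v - cur) * heading > 0]
        return forward[0] if forward else nbrs[0]
    options = [v for v in nbrs if v != prev]
    if not options:
        return prev  # dead end
    if len(options) == 1:
        return options[0]
    hvec = net.coords[cur] - net.coords[prev]
    hnorm = math.hypot(*hvec)
    best = None
    for v in options:
        evec = net.coords[v] - net.coords[cur]
        enorm = math.hypot(*evec)
        cosang = (float(np.dot(hvec, evec)) / (hnorm * enorm)
                  if hnorm > 0 and enorm > 0 else 0.0)
        key = (-cosang, v)
        if best is None or key < best:
            best = key
    return int(best[1])


def _bias_path(net: LandscapeNetwork, origin: int, target: int,
               search_m: float):
    """Shortest path origin -> target (list of points after origin), using
    the deterministic BFS tree; widens the search until the target is found."""
    radius = search_m
    while True:
        reach = _bfs_within(net, origin, radius)
        if target in reach:
            break
        if len(reach) >= net.n_points:
            raise ParameterError("bias target unreachable")
        radius *= 2
    path = []
    cur = target
    while cur != origin:
        path.append(cur)
        cur = reach[cur][1]
    path.reverse()
    return path


def traverse(otter, net: LandscapeNetwork, schools, distance_budget_m: float,
             bias, p: BehaviorParams, rng=None):
    """Move along the network in 10-m steps for up to the hour's budget.

    With a bias target the otter follows the shortest path and stops on
    arrival; without one it continues its heading, turning minimally at
    junctions.  Movement also stops the first time an active fish school
    lies within the visual-perception distance.  ``schools`` is a set of
    point ids occupied by schools this hour.

    Returns ``(new_position, encountered_school, path)`` where ``path``
    includes every visited point (origin first).
    """
    if distance_budget_m < 0:
        raise ParameterError("distance_budget_m must be >= 0")
    pos, prev = otter.position, otter.prev_point
    path = [pos]
    if _school_in_sight(net, pos, schools, p):
        return pos, True, path
    steps = int(distance_budget_m // 10.0)
    plan = (_bias_path(net, pos, int(bias), p.memory_m)
            if bias is not None and bias != pos else None)
    encountered = False
    for k in range(steps):
        if plan is not None:
            if k >= len(plan):
                break          # arrived at the bias target
            nxt = plan[k]
        else:
            nxt = _next_crw_step(net, pos, prev, otter.heading)
        prev, pos = pos, nxt
        path.append(pos)
        if _school_in_sight(net, pos, schools, p):
            encountered = True
            break
    if pos != otter.position:
        otter.heading = 1 if pos > prev else -1
        otter.prev_point = prev
    otter.position = pos
    return pos, encountered, path


def _school_in_sight(net, pos, schools, p):
    if not schools:
        return False
    reach = _bfs_within(net, pos, p.visual_m)
    return any(pt in reach for pt in schools)


# ----------------------------------------------------------------------
# Bookkeeping
# ----------------------------------------------------------------------

def deposit_feces(otter, net: LandscapeNetwork, p: BehaviorParams,
                  hour: int, deposits: list) -> FecalDeposit:
    """Record one deposit at the nearest highest-quality latrine in memory
    range of the otter's position (or at the position itself if none)."""
    reach = _bfs_within(net, otter.position, p.memory_m)
    site = _nearest_best_latrine_bfs(net, reach)
    if site is None:
        site = otter.position
    dep = FecalDeposit(id=len(deposits), otter_id=otter.id, point=int(site),
                       hour=int(hour), pelagic=bool(otter.satiated))
    deposits.append(dep)
    return dep


def end_of_hour_update(otter, encountered: bool, defecated: bool,
                       switched: bool):
    """Advance the otter's clocks and flags at the end of an hour."""
    if encountered:
        otter.satiated = True
        otter.encounters += 1
    if defecated:
        if otter.satiated:
            otter.satiated = False   # the pelagic meal is voided
        otter.hours_since_defecation = 0
    else:
        otter.hours_since_defecation += 1
    if switched:
        otter.hours_in_state = 0
    else:
        otter.hours_in_state += 1
    return otter
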