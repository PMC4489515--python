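"""Draw the simulated otter population and its initial states.

Abundance inside the study area is drawn from a discrete uniform between
recent density estimates (55-78 resident otters); the out-of-area
population is added by multiplying that draw by 0.585 and rounding.  Each
otter receives a sex (Bernoulli, 69% male), an initial activity state
(Bernoulli with probability equal to the ratio of mean active to mean
inactive hours), integer clocks for hours-in-state and hours-since-last-
defecation, and a network position on latrine-grade habitat
(``mep > 0.464``).  Females additionally receive an exclusive 50% core
home-range interval: length drawn from a normal(4 km, 2 km) truncated to
positive values, centred on a latrine-grade point such that no two female
core intervals overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

import scipy.sparse.csgraph as _csgraph

from .errors import ParameterError, CapacityError
from .landscape import LandscapeNetwork


@dataclass
class InitParams:
    """Initialization parameters; defaults follow the field estimates."""

    density_min: int = 55
    density_max: int = 78
    out_of_area_factor: float = 0.585
    male_fraction: float = 0.69
    female_core_mean_km: float = 4.0
    female_core_sd_km: float = 2.0
    activity_threshold: float = 0.122
    active_upper_ci_h: float = 1.88
    inactive_upper_ci_h: float = 15.32
    defecation_clock_max_h: float = 5.0
    mep_placement_threshold: float = 0.464
    max_placement_attempts: int = 10_000

    def __post_init__(self):
        if self.density_min > self.density_max:
            raise ParameterError("density_min must be <= density_max")
        for name in ("male_fraction", "activity_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0,1], got {v}")
        for name in ("female_core_mean_km", "female_core_sd_km",
                     "active_upper_ci_h", "inactive_upper_ci_h",
                     "defecation_clock_max_h"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class OtterState:
    """Mutable per-agent state carried through the hourly simulation."""

    id: int
    sex: str                       # "male" | "female"
    activity: str                  # "active" | "inactive"
    hours_in_state: int
    hours_since_defecation: int
    satiated: bool = False
    position: int = -1             # network point id; -1 = unplaced
    heading: int = 1               # +1 / -1 along coastline point ordering
    prev_point: int = -1           # last point traversed from (engine detail)
    home_center: Optional[int] = None     # females only
    core_length_m: Optional[float] = None  # females only
    encounters: int = 0
    in_study_area: bool = True

    def __post_init__(self):
        if self.hours_in_state < 0 or self.hours_since_defecation < 0:
            raise ParameterError("state clocks must be >= 0")


def compute_activity_threshold(mean_active_h: float,
                               mean_inactive_h: float) -> float:
    """Probability of starting active: ratio of mean active to inactive hours."""
    if mean_active_h <= 0 or mean_inactive_h <= 0:
        raise ParameterError("mean state durations must be > 0")
    return mean_active_h / mean_inactive_h


def draw_population_size(params: InitParams, rng: np.random.Generator):
    """Draw (study_area_n, total_n).

    ``study_area_n`` is discrete uniform on [density_min, density_max];
    the total adds the out-of-area extrapolation
    ``round(study_area_n * out_of_area_factor)``.
    """
    study_n = int(rng.integers(params.density_min, params.density_max + 1))
    total_n = study_n + int(round(study_n * params.out_of_area_factor))
    return study_n, total_n


def init_otter_states(total_n: int, params: InitParams,
                      rng: np.random.Generator) -> list[OtterState]:
    """Draw sexes, activity states and clocks for ``total_n`` otters.

    Positions are left unset; use :func:`assign_female_cores` and
    :func:`place_otters` afterwards.
    """
    if total_n < 1:
        raise ParameterError("total_n must be >= 1")
    otters = []
    for i in range(total_n):
        sex = "male" if rng.random() < params.male_fraction else "female"
        active = rng.random() < params.activity_threshold
        upper = (params.active_upper_ci_h if active
                 else params.inactive_upper_ci_h)
        hours_state = int(round(rng.uniform(0.0, upper)))
        hours_defec = int(round(rng.uniform(0.0, params.defecation_clock_max_h)))
        otters.append(OtterState(
            id=i, sex=sex, activity="active" if active else "inactive",
            hours_in_state=hours_state, hours_since_defecation=hours_defec))
    return otters


def _truncated_positive_normal(mean, sd, rng):
    # literal rejection sampling: redraw until the value is positive
    while True:
        v = rng.normal(mean, sd)
        if v > 0:
            return v


def assign_female_cores(net: LandscapeNetwork, females: list[OtterState],
                        params: InitParams, rng: np.random.Generator,
                        eligible_masks=None) -> list[OtterState]:
    """Assign core lengths and mutually exclusive home centres to females.

    Core length ~ Normal(4 km, 2 km) truncated to positive values (rejection
    sampled), scaled by the radial-extent factor at the chosen centre.
    Centres are drawn uniformly from latrine-grade points (optionally
    restricted per female by ``eligible_masks``); a candidate is accepted
    only if its core interval (half the core length each side) overlaps no
    previously placed female core, i.e. the centre-to-centre network
    distance is at least the sum of the half-lengths.  Placement order is a
    random permutation so low ids gain no systematic advantage.
    """
    placed: list[tuple[int, float]] = []   # (center, half_length_m)
    order = rng.permutation(len(females))
    latrine = net.is_latrine
    for idx in order:
        f = females[idx]
        if f.sex != "female":
            raise ParameterError(f"otter {f.id} is not female")
        mask = latrine if eligible_masks is None else (latrine
                                                       & eligible_masks[idx])
        candidates = np.flatnonzero(mask)
        if len(candidates) == 0:
            raise CapacityError(f"no latrine-grade point available for "
                                f"female {f.id}")
        core_m = _truncated_positive_normal(
            params.female_core_mean_km * 1000.0,
            params.female_core_sd_km * 1000.0, rng)
        ok = False
        sparse = net._sparse()
        max_half = max((h for _, h in placed), default=0.0)
        for attempt in range(params.max_placement_attempts):
            # on a crowded coastline a large core may fit nowhere: redraw
            # the core length periodically within the attempt budget
            if attempt and attempt % 50 == 0:
                core_m = _truncated_positive_normal(
                    params.female_core_mean_km * 1000.0,
                    params.female_core_sd_km * 1000.0, rng)
            center = int(candidates[rng.integers(len(candidates))])
            half = 0.5 * core_m * float(net.radial_scale[center])
            if not placed:
                ok = True
                break
            # cutoff Dijkstra: centres beyond half+max_half cannot overlap
            dist = _csgraph.dijkstra(sparse, directed=False, indices=center,
                                     limit=half + max_half)
            if all(dist[c] >= half + h for c, h in placed):
                ok = True
                break
        if not ok:
            raise CapacityError(
                f"could not place non-overlapping core for female {f.id} "
                f"after {params.max_placement_attempts} attempts")
        placed.append((center, half))
        f.home_center = center
        f.core_length_m = core_m * float(net.radial_scale[center])
    return females


def place_otters(net: LandscapeNetwork, otters: list[OtterState],
                 params: InitParams, rng: np.random.Generator,
                 study_area_n: Optional[int] = None) -> list[OtterState]:
    """Place every otter on a latrine-grade point.

    The first ``study_area_n`` otters form the study-area subpopulation and
    are placed on in-study-area points; the remainder go outside.  Females
    start at their home centre; males draw a uniform eligible point.
    Initial heading is uniform on {+1, -1}.
    """
    if study_area_n is None:
        study_area_n = len(otters)
    eligible = net.mep > params.mep_placement_threshold
    pools = {
        True: np.flatnonzero(eligible & net.in_study_area),
        False: np.flatnonzero(eligible & ~net.in_study_area),
    }
    for k, o in enumerate(otters):
        in_study = k < study_area_n
        o.in_study_area = in_study
        pool = pools[in_study]
        if len(pool) == 0:
            raise CapacityError(
                "no eligible point (mep > "
                f"{params.mep_placement_threshold}) in the "
                f"{'study-area' if in_study else 'outside'} region")
        if o.sex == "female" and o.home_center is not None:
            o.position = int(o.home_center)
        else:
            o.position = int(pool[rng.integers(len(pool))])
        o.heading = 1 if rng.random() < 0.5 else -1
    return otters


def initialize_population(net: LandscapeNetwork, params: InitParams,
                          rng: np.random.Generator):
    """Full initialization pipeline; returns ``(otters, study_area_n)``."""
    study_n, total_n = draw_population_size(params, rng)
    otters = init_otter_states(total_n, params, rng)
    eligible = net.mep > params.mep_placement_threshold
    fem_idx = [i for i, o in enumerate(otters) if o.sex == "female"]
    females = [otters[i] for i in fem_idx]
    masks = [net.in_study_area if i < study_n else ~net.in_study_area
             for i in fem_idx]
    if females:
        assign_female_cores(net, females, params, rng, eligible_masks=masks)
    place_otters(net, otters, params, rng, study_area_n=study_n)
    return otters, study_n
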