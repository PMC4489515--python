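"""Hourly schooling-fish field for the six availability scenarios.

Schooling pelagic fish (herring, sand lance, salmonids) enter the
nearshore zone to spawn between mid-May and mid-August.  Each replicate
draws a season maximum of 40-98 schools; the hourly count scales that
maximum by the scenario availability multiplier and a seasonal weight, and
schools are re-placed uniformly at random every hour on eligible
coastline points (spawning habitat when the scenario is
spawn-constrained).  Schools are not depleted by otter feeding: any number
of otters may encounter the same school within an hour, which is the
mechanism that lets foraging groups form.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError, ConfigurationError
from .landscape import LandscapeNetwork

#: Length of the simulated season (May 15 00:00 to Aug 16 00:00), days.
SEASON_DAYS = 93
SEASON_HOURS = SEASON_DAYS * 24


@dataclass(frozen=True)
class ScenarioConfig:
    """One schooling-fish scenario."""

    name: str
    availability: float = 1.0          # multiplier in [0, 1]
    spawn_constrained: bool = True
    school_min: int = 40
    school_max: int = 98
    season_days: int = SEASON_DAYS
    seasonal_weight: str = "triangular"   # or "constant"

    def __post_init__(self):
        if not 0.0 <= self.availability <= 1.0:
            raise ParameterError("availability must be in [0,1]")
        if self.school_min > self.school_max:
            raise ParameterError("school_min must be <= school_max")
        if self.seasonal_weight not in ("triangular", "constant"):
            raise ParameterError(
                f"unknown seasonal weight {self.seasonal_weight!r}")


@dataclass(frozen=True)
class FishSchool:
    id: int
    point: int
    hour: int


#: The six named scenario presets.
SCENARIOS = {
    "School_100%": ScenarioConfig("School_100%", 1.0, True),
    "School_Random": ScenarioConfig("School_Random", 1.0, False),
    "School_75%": ScenarioConfig("School_75%", 0.75, True),
    "School_50%": ScenarioConfig("School_50%", 0.50, True),
    "School_25%": ScenarioConfig("School_25%", 0.25, True),
    "School_None": ScenarioConfig("School_None", 0.0, True),
}
#: Alias used in the field literature for the random-placement baseline.
SCENARIOS["Random_100%"] = SCENARIOS["School_Random"]


def get_scenario(name: str) -> ScenarioConfig:
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {name!r}; choose from "
            f"{sorted(set(s.name for s in SCENARIOS.values()))}") from None


def draw_season_max(cfg: ScenarioConfig, rng: np.random.Generator) -> int:
    """Season maximum number of schools, discrete uniform on
    [school_min, school_max]; drawn once per replicate."""
    return int(rng.integers(cfg.school_min, cfg.school_max + 1))


def seasonal_weight(cfg: ScenarioConfig, day_index: int) -> float:
    """Within-season availability weight w(day) in (0, 1].

    Default is a symmetric triangular ramp from 0.5 at the season edges to
    1.0 at mid-season; a constant weight of 1 is also selectable.  The
    shape is a declared placeholder for the (unpublished) empirical
    spawning phenology; season-aggregated metrics are insensitive to mild
    shape changes.
    """
    if not 0 <= day_index < cfg.season_days:
        raise ParameterError(f"day_index {day_index} outside season")
    if cfg.seasonal_weight == "constant":
        return 1.0
    mid = (cfg.season_days - 1) / 2.0
    return 0.5 + 0.5 * (1.0 - abs(day_index - mid) / mid)


def hourly_school_count(cfg: ScenarioConfig, season_max: int,
                        day_index: int) -> int:
    """Number of schools present during any hour of the given day:
    ``round(season_max * availability * w(day))`` (half-up rounding)."""
    w = seasonal_weight(cfg, day_index)
    return int(season_max * cfg.availability * w + 0.5)


def eligible_points(net: LandscapeNetwork, cfg: ScenarioConfig) -> np.ndarray:
    """Coastline points where schools may appear under this scenario."""
    mask = ~net.on_virtual_line
    if cfg.spawn_constrained:
        mask = mask & net.spawn_habitat
    pts = np.flatnonzero(mask)
    if cfg.spawn_constrained and cfg.availability > 0 and len(pts) == 0:
        raise ConfigurationError(
            f"scenario {cfg.name!r} requires spawning habitat but the "
            "network has none")
    return pts


def place_schools(net: LandscapeNetwork, cfg: ScenarioConfig, n: int,
                  rng: np.random.Generator, hour: int = 0):
    """Place ``n`` schools uniformly at random on eligible points."""
    if n == 0:
        return []
    pts = eligible_points(net, cfg)
    draws = pts[rng.integers(0, len(pts), size=n)]
    return [FishSchool(id=i, point=int(p), hour=hour)
            for i, p in enumerate(draws)]


def build_school_schedule(net: LandscapeNetwork, cfg: ScenarioConfig,
                          rng: np.random.Generator):
    """Pre-draw the whole season's school field for one replicate.

    Returns ``(season_max, counts, points)`` where ``counts[h]`` is the
    number of schools in hour ``h`` and ``points[h, :counts[h]]`` their
    point ids.  Positions are resampled every hour (1-h residence time).
    """
    season_max = draw_season_max(cfg, rng)
    hours = cfg.season_days * 24
    counts = np.zeros(hours, dtype=np.int32)
    points = np.full((hours, cfg.school_max), -1, dtype=np.int32)
    pts = eligible_points(net, cfg) if cfg.availability > 0 else None
    for h in range(hours):
        n = hourly_school_count(cfg, season_max, h // 24)
        counts[h] = n
        if n:
            points[h, :n] = pts[rng.integers(0, len(pts), size=n)]
    return season_max, counts, points
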