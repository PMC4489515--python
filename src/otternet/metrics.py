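"""Emergent response variables computed from replicate logs.

Per-otter rates (defecation, activity, school encounters), social-group
statistics (a "group" is a connected component of two or more active
otters within a proximity radius of network distance), the pelagic-fish
content of feces, 1-D core home-range length, 50-m-window deposition
totals with hotspot classes, and the annual marine-derived-nitrogen
transport implied by a deposition rate.  Cross-replicate values are
reported as mean with a normal-approximation 95% confidence interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse.csgraph as _csgraph

from .errors import ParameterError
from .landscape import LandscapeNetwork, POINT_SPACING_M

#: Grams of nitrogen per fecal deposit (captive-diet estimate).
N_GRAMS_PER_DEPOSIT = 5.15

#: Default group proximity: 10 point-locations of network distance.
DEFAULT_GROUP_PROXIMITY_M = 100.0


def mean_ci(values, level: float = 0.95):
    """Mean and normal-approximation CI half-width over replicates."""
    v = np.asarray(values, dtype=float)
    m = float(v.mean())
    if len(v) < 2:
        return m, m, m
    se = float(v.std(ddof=1)) / np.sqrt(len(v))
    z = 1.959963984540054 if level == 0.95 else \
        float(abs(np.round(_z_for(level), 12)))
    return m, m - z * se, m + z * se


def _z_for(level):
    from scipy.stats import norm
    return norm.ppf(0.5 + level / 2.0)


def _as_logs(logs):
    return [logs] if not isinstance(logs, (list, tuple)) else list(logs)


# ----------------------------------------------------------------------
# Rates
# ----------------------------------------------------------------------

def defecation_rate(log, by_sex: bool = False):
    """Proportion of simulated hours with a defecation event, per otter,
    averaged overall (or within each sex)."""
    if log.n_hours == 0 or log.n_otters == 0:
        raise ParameterError("empty replicate log")
    rates = log.defecations / float(log.n_hours)
    if not by_sex:
        return float(rates.mean())

    def _mean(sel):
        return float(sel.mean()) if len(sel) else float("nan")

    return {"female": _mean(rates[~log.is_male]),
            "male": _mean(rates[log.is_male]),
            "overall": float(rates.mean())}


def mean_feces_per_day(logs):
    """Per-replicate total deposits per season day; mean and 95% CI."""
    logs = _as_logs(logs)
    vals = [log.n_deposits / (log.n_hours / 24.0) for log in logs]
    return mean_ci(vals)


def pct_pelagic_feces(log) -> float:
    """Percent of deposits containing pelagic fish (laid while satiated)."""
    if log.n_deposits == 0:
        raise ParameterError("no deposits in log")
    return 100.0 * float(log.dep_pelagic.astype(bool).mean())


def school_encounters(log, by_sex: bool = False):
    """Mean number of successful fish-school encounters per otter."""
    if not by_sex:
        return float(log.encounters.mean())
    return {"female": float(log.encounters[~log.is_male].mean()),
            "male": float(log.encounters[log.is_male].mean())}


# ----------------------------------------------------------------------
# Social groups
# ----------------------------------------------------------------------

def detect_groups(log, hour: int,
                  proximity_m: float = DEFAULT_GROUP_PROXIMITY_M):
    """Groups at one hour: connected components (size >= 2) of the graph
    linking active otters within ``proximity_m`` network distance."""
    if proximity_m < 0:
        raise ParameterError("proximity_m must be >= 0")
    from .engine import detect_groups_from_arrays
    return detect_groups_from_arrays(
        log.net, log.state_log[:, hour].astype(bool),
        log.pos_log[:, hour], proximity_m)


def group_metrics(logs, proximity_m: float | None = None) -> pd.DataFrame:
    """Cross-replicate group statistics.

    Uses the tallies accumulated during the run (at the proximity radius
    the replicate was run with); pass ``proximity_m`` only to force a
    (slow) recomputation at a different radius.
    """
    logs = _as_logs(logs)
    rows = []
    for log in logs:
        if proximity_m is not None and \
                proximity_m != log.meta.get("group_proximity_m"):
            acc, ngh, grouped, mixed = _recompute_groups(log, proximity_m)
        else:
            acc, ngh = log.group_accum, log.n_groups_hour
            grouped, mixed = log.grouped_hours, log.mixed_hours
        members, groups, gmin, gmax = [int(x) for x in acc]
        act_f = float(log.active_hours[~log.is_male].sum())
        act_m = float(log.active_hours[log.is_male].sum())
        grp_f = float(grouped[~log.is_male].sum())
        grp_m = float(grouped[log.is_male].sum())
        rows.append({
            "n_groups": float(np.mean(ngh)),
            "mean_group_size": members / groups if groups else np.nan,
            "max_group_size": gmax if groups else np.nan,
            "min_group_size": gmin if groups else np.nan,
            "pct_time_in_group_female": 100.0 * grp_f / act_f if act_f else 0.0,
            "pct_time_in_group_male": 100.0 * grp_m / act_m if act_m else 0.0,
            "pct_mixed_female": (100.0 * mixed[~log.is_male].sum() / grp_f
                                 if grp_f else np.nan),
            "pct_mixed_male": (100.0 * mixed[log.is_male].sum() / grp_m
                               if grp_m else np.nan),
        })
    return pd.DataFrame(rows)


def _recompute_groups(log, proximity_m):
    acc = np.zeros(4, dtype=np.int64)
    acc[2] = 1 << 30
    ngh = np.zeros(log.n_hours, dtype=np.int32)
    grouped = np.zeros(log.n_otters, dtype=np.int64)
    mixed = np.zeros(log.n_otters, dtype=np.int64)
    for h in range(log.n_hours):
        groups = detect_groups(log, h, proximity_m)
        ngh[h] = len(groups)
        acc[1] += len(groups)
        for g in groups:
            acc[0] += len(g)
            acc[2] = min(acc[2], len(g))
            acc[3] = max(acc[3], len(g))
            has_m = any(log.is_male[i] for i in g)
            has_f = any(not log.is_male[i] for i in g)
            for i in g:
                grouped[i] += 1
                if has_m and has_f:
                    mixed[i] += 1
    return acc, ngh, grouped, mixed


# ----------------------------------------------------------------------
# Home range
# ----------------------------------------------------------------------

def core_range_length(log, otter_id: int, quantile: float = 0.5,
                      bandwidth_m: float = 300.0) -> float:
    """1-D network utilization-distribution core length, km.

    Hourly positions give a time-weighted occupancy mass per point; the
    mass is smoothed along the network with a Gaussian kernel of the given
    bandwidth, and the returned value is the shoreline length (number of
    points x 10 m) of the smallest point set containing ``quantile`` of
    the smoothed mass.
    """
    if not 0 < quantile <= 1:
        raise ParameterError("quantile must be in (0, 1]")
    positions = log.pos_log[otter_id]
    if len(positions) == 0:
        raise ParameterError("otter has no logged positions")
    counts = np.bincount(positions, minlength=log.net.n_points).astype(float)
    occupied = np.flatnonzero(counts)
    density = np.zeros(log.net.n_points)
    sparse = log.net._sparse()
    cutoff = 3.0 * bandwidth_m
    for chunk in np.array_split(occupied, max(1, len(occupied) // 200)):
        d = _csgraph.dijkstra(sparse, directed=False, indices=chunk,
                              limit=cutoff)
        w = np.where(np.isfinite(d),
                     np.exp(-0.5 * (d / bandwidth_m) ** 2), 0.0)
        density += counts[chunk] @ w
    order = np.argsort(-density, kind="stable")
    cum = np.cumsum(density[order])
    k = int(np.searchsorted(cum, quantile * cum[-1])) + 1
    return k * POINT_SPACING_M / 1000.0


# ----------------------------------------------------------------------
# Deposition windows and hotspots
# ----------------------------------------------------------------------

def window_counts(deposits, net: LandscapeNetwork,
                  window_points: int = 5) -> pd.DataFrame:
    """Deposit totals over non-overlapping runs of ``window_points``
    consecutive points (50 m by default).

    Coastline points are windowed in id order; virtual-line points are
    windowed separately afterwards, so the window totals partition the
    deposits exactly.  ``deposits`` is a point-id array or a DataFrame
    with a ``point_id`` column.
    """
    if window_points < 1:
        raise ParameterError("window_points must be >= 1")
    if isinstance(deposits, pd.DataFrame):
        pts = deposits["point_id"].to_numpy()
    else:
        pts = np.asarray(deposits, dtype=np.int64)
    per_point = np.bincount(pts, minlength=net.n_points) if len(pts) else \
        np.zeros(net.n_points, dtype=np.int64)
    rows = []
    wid = 0
    for coast, ids in ((True, np.flatnonzero(~net.on_virtual_line)),
                       (False, np.flatnonzero(net.on_virtual_line))):
        for start in range(0, len(ids), window_points):
            sel = ids[start:start + window_points]
            rows.append((wid, int(sel[0]), bool(coast),
                         int(per_point[sel].sum())))
            wid += 1
    return pd.DataFrame(rows, columns=["window_id", "start_id",
                                       "is_coast", "count"])


def hotspot_classify(window_total: int) -> str:
    """Deposition class of a 50-m window total: >150 deposits is a
    hotspot, 50-150 inclusive intermediate, <50 background."""
    if window_total < 0:
        raise ParameterError("window_total must be >= 0")
    if window_total > 150:
        return "hotspot"
    if window_total >= 50:
        return "intermediate"
    return "background"


def hotspot_proportions(windows: pd.DataFrame) -> dict:
    """Proportion of coastline windows in each deposition class."""
    coast = windows[windows["is_coast"]]
    classes = coast["count"].map(hotspot_classify)
    n = len(coast)
    return {c: float((classes == c).sum()) / n
            for c in ("hotspot", "intermediate", "background")}


# ----------------------------------------------------------------------
# Nutrient transport
# ----------------------------------------------------------------------

def annual_nitrogen_kg(mean_feces_per_day: float,
                       g_per_deposit: float = N_GRAMS_PER_DEPOSIT) -> float:
    """Annual nitrogen mass (kg) moved to land at the given deposition
    rate, at ``g_per_deposit`` grams of N per deposit."""
    if mean_feces_per_day < 0:
        raise ParameterError("rate must be >= 0")
    return mean_feces_per_day * 365.0 * g_per_deposit / 1000.0


# ----------------------------------------------------------------------
# Scenario-level summary
# ----------------------------------------------------------------------

def scenario_summary(logs, include_core_range: bool = False) -> pd.DataFrame:
    """Cross-replicate mean and 95% CI for every emergent metric.

    Returns a tidy frame with one row per metric: mean, ci_lo, ci_hi.
    """
    logs = _as_logs(logs)
    per_rep = {}

    def add(name, vals):
        per_rep[name] = np.asarray(vals, dtype=float)

    add("abundance", [log.n_otters for log in logs])
    for key, mask_fn in (("", None),
                         ("_female", lambda l: ~l.is_male),
                         ("_male", lambda l: l.is_male)):
        add("defecation_rate" + key,
            [(log.defecations if mask_fn is None
              else log.defecations[mask_fn(log)]).mean() / log.n_hours
             for log in logs])
        add("school_encounters" + key,
            [(log.encounters if mask_fn is None
              else log.encounters[mask_fn(log)]).mean() for log in logs])
        add("active_hours" + key,
            [(log.active_hours if mask_fn is None
              else log.active_hours[mask_fn(log)]).mean() for log in logs])
    add("mean_feces_per_day",
        [log.n_deposits / (log.n_hours / 24.0) for log in logs])
    add("pct_pelagic_feces",
        [100.0 * log.dep_pelagic.astype(bool).mean()
         if log.n_deposits else 0.0 for log in logs])
    gm = group_metrics(logs)
    for col in gm.columns:
        add(col, gm[col].to_numpy())
    hp = [hotspot_proportions(window_counts(log.dep_point, log.net))
          for log in logs]
    for c in ("hotspot", "intermediate", "background"):
        add(f"prop_windows_{c}", [h[c] for h in hp])
    add("annual_N_kg",
        [annual_nitrogen_kg(log.n_deposits / (log.n_hours / 24.0))
         for log in logs])
    if include_core_range:
        for key, female in (("_female", True), ("_male", False)):
            vals = []
            for log in logs:
                ids = np.flatnonzero(log.is_male != female)
                vals.append(np.mean([core_range_length(log, int(i))
                                     for i in ids]) if len(ids) else np.nan)
            add("core_range_km" + key, vals)

    rows = []
    for name, vals in per_rep.items():
        vals = vals[~np.isnan(vals)] if np.isnan(vals).any() else vals
        if len(vals) == 0:
            rows.append((name, np.nan, np.nan, np.nan))
            continue
        m, lo, hi = mean_ci(vals)
        rows.append((name, m, lo, hi))
    return pd.DataFrame(rows, columns=["metric", "mean", "ci_lo", "ci_hi"])
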