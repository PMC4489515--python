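"""Linear landscape network: 10-m coastline point-locations plus corridor edges.

All otter movement, perception and fecal deposition happen on this 1-D
network.  Each point-location carries the habitat state variables used by
the behavioural model: a habitat-quality score (``mep``, the probability the
point is an otter latrine, in [0, 1]), a radial-extent scaling factor, a
spawning-habitat flag (shallow shoreline where schooling fish may appear)
and an in-study-area flag.  "Virtual line" points form travel corridors
between stretches of coastline; they are traversable but carry ``mep = 0``
and no spawning habitat, so they are never latrines or school sites.

Coordinates are planar metres with no geodesy: the network itself is the
sole movement space, and all distances are shortest-path distances along
its edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import os

import numpy as np
import networkx as nx
from scipy.ndimage import gaussian_filter1d
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .errors import ParameterError, FormatError

#: Fixed spacing of point-locations along the network, metres.
POINT_SPACING_M = 10.0

#: Default habitat-quality cutoff above which a point counts as a latrine.
DEFAULT_LATRINE_THRESHOLD = 0.464


@dataclass
class PointLocation:
    """One 10-m point-location and its habitat state variables."""

    id: int
    coord: tuple[float, float]
    mep: float
    radial_scale: float = 1.0
    spawn_habitat: bool = False
    in_study_area: bool = True
    on_virtual_line: bool = False

    def __post_init__(self):
        if not 0.0 <= self.mep <= 1.0:
            raise ParameterError(f"mep must be in [0,1], got {self.mep}")
        if self.radial_scale <= 0:
            raise ParameterError("radial_scale must be > 0")


class LandscapeNetwork:
    """The 10-m-resolution linear network with per-point habitat state.

    Parameters are parallel arrays over point ids ``0..n-1``.  ``edges`` is a
    sequence of ``(u, v, length_m)``; in networks produced by the synthetic
    generator every edge is exactly 10 m.  ``segments`` lists the point-id
    chains (coastline pieces and corridors) used for serialization and for
    the 50-m window ordering; it is reconstructed by chain-walking when not
    supplied.
    """

    def __init__(self, coords, mep, radial_scale, spawn_habitat,
                 in_study_area, on_virtual_line, edges,
                 latrine_threshold: float = DEFAULT_LATRINE_THRESHOLD,
                 segments=None):
        self.coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
        n = len(self.coords)
        self.mep = np.asarray(mep, dtype=np.float64)
        self.radial_scale = np.asarray(radial_scale, dtype=np.float64)
        self.spawn_habitat = np.asarray(spawn_habitat, dtype=bool)
        self.in_study_area = np.asarray(in_study_area, dtype=bool)
        self.on_virtual_line = np.asarray(on_virtual_line, dtype=bool)
        for name in ("mep", "radial_scale", "spawn_habitat",
                     "in_study_area", "on_virtual_line"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"field {name!r} has length "
                                     f"{len(getattr(self, name))}, expected {n}")
        if np.any((self.mep < 0) | (self.mep > 1)):
            raise ParameterError("mep values must lie in [0,1]")
        if np.any(self.radial_scale <= 0):
            raise ParameterError("radial_scale values must be > 0")
        edges = [(int(e[0]), int(e[1]), float(e[2])) for e in edges]
        self.edge_index = np.array([(u, v) for u, v, _ in edges],
                                   dtype=np.int64).reshape(-1, 2)
        self.edge_length = np.array([w for _, _, w in edges], dtype=np.float64)
        if len(self.edge_index) and (self.edge_index.min() < 0
                                     or self.edge_index.max() >= n):
            raise ParameterError("edge endpoint outside point range")
        self.latrine_threshold = float(latrine_threshold)
        self._segments = ([np.asarray(s, dtype=np.int64) for s in segments]
                          if segments is not None else None)
        self._graph = None
        self._csr = None

    # ------------------------------------------------------------------
    # Basic views
    # ------------------------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.coords)

    @property
    def is_latrine(self) -> np.ndarray:
        """Boolean mask of latrine-grade points (``mep > latrine_threshold``)."""
        return self.mep > self.latrine_threshold

    @property
    def coastline_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.on_virtual_line)

    @property
    def study_area_fraction(self) -> float:
        """Fraction of coastline points flagged in-study-area."""
        coast = ~self.on_virtual_line
        return float(self.in_study_area[coast].mean())

    @property
    def uniform_10m(self) -> bool:
        """True when every edge is exactly one point-spacing long."""
        return bool(np.allclose(self.edge_length, POINT_SPACING_M))

    def point(self, i: int) -> PointLocation:
        return PointLocation(
            id=int(i), coord=tuple(self.coords[i]), mep=float(self.mep[i]),
            radial_scale=float(self.radial_scale[i]),
            spawn_habitat=bool(self.spawn_habitat[i]),
            in_study_area=bool(self.in_study_area[i]),
            on_virtual_line=bool(self.on_virtual_line[i]))

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(self.n_points))
            g.add_weighted_edges_from(
                (int(u), int(v), float(w))
                for (u, v), w in zip(self.edge_index, self.edge_length))
            self._graph = g
        return self._graph

    def csr_adjacency(self):
        """CSR neighbour arrays ``(indptr, neighbours, edge_lengths)`` with
        neighbour lists sorted by id (the engine relies on this ordering)."""
        if self._csr is None:
            n = self.n_points
            u = np.concatenate([self.edge_index[:, 0], self.edge_index[:, 1]])
            v = np.concatenate([self.edge_index[:, 1], self.edge_index[:, 0]])
            w = np.concatenate([self.edge_length, self.edge_length])
            order = np.lexsort((v, u))
            u, v, w = u[order], v[order], w[order]
            indptr = np.zeros(n + 1, dtype=np.int64)
            np.add.at(indptr, u + 1, 1)
            indptr = np.cumsum(indptr)
            self._csr = (indptr.astype(np.int64), v.astype(np.int32),
                         w.astype(np.float64))
        return self._csr

    def _sparse(self):
        indptr, nbr, wlen = self.csr_adjacency()
        return csr_matrix((wlen, nbr, indptr),
                          shape=(self.n_points, self.n_points))

    @property
    def segments(self):
        if self._segments is None:
            self._segments = _walk_segments(self)
        return self._segments

    def validate(self) -> None:
        """Raise if a structural invariant is violated."""
        if not nx.is_connected(self.graph):
            raise ParameterError("landscape network must be connected")
        if not np.any(self.is_latrine):
            raise ParameterError("no latrine-grade points "
                                 f"(mep > {self.latrine_threshold})")

    def __eq__(self, other):
        if not isinstance(other, LandscapeNetwork):
            return NotImplemented
        return (np.array_equal(self.coords, other.coords)
                and np.array_equal(self.mep, other.mep)
                and np.array_equal(self.radial_scale, other.radial_scale)
                and np.array_equal(self.spawn_habitat, other.spawn_habitat)
                and np.array_equal(self.in_study_area, other.in_study_area)
                and np.array_equal(self.on_virtual_line, other.on_virtual_line)
                and _edge_set(self) == _edge_set(other)
                and self.latrine_threshold == other.latrine_threshold)


def _edge_set(net: LandscapeNetwork):
    return {(min(u, v), max(u, v), w)
            for (u, v), w in zip(net.edge_index, net.edge_length)}


def _walk_segments(net: LandscapeNetwork):
    """Decompose the graph into maximal chains of degree-2 interior points."""
    indptr, nbr, _ = net.csr_adjacency()
    deg = np.diff(indptr)
    seen = set()
    segments = []

    def neighbours(i):
        return nbr[indptr[i]:indptr[i + 1]]

    # chains anchored at junctions/dead-ends
    for start in np.flatnonzero(deg != 2):
        for nxt in neighbours(start):
            key = (min(start, nxt), max(start, nxt))
            if key in seen:
                continue
            chain = [int(start), int(nxt)]
            seen.add(key)
            while deg[chain[-1]] == 2:
                a, b = neighbours(chain[-1])
                step = int(a) if int(b) == chain[-2] else int(b)
                seen.add((min(chain[-1], step), max(chain[-1], step)))
                chain.append(step)
            segments.append(np.array(chain, dtype=np.int64))
    # pure cycles (no junction anchor)
    for (u, v), _w in zip(net.edge_index, net.edge_length):
        key = (min(u, v), max(u, v))
        if key in seen:
            continue
        chain = [int(u), int(v)]
        seen.add(key)
        while chain[-1] != chain[0]:
            a, b = neighbours(chain[-1])
            step = int(a) if int(b) == chain[-2] else int(b)
            seen.add((min(chain[-1], step), max(chain[-1], step)))
            chain.append(step)
        segments.append(np.array(chain, dtype=np.int64))
    return segments


# ----------------------------------------------------------------------
# Geometric queries
# ----------------------------------------------------------------------

def network_distance(net: LandscapeNetwork, a: int, b: int) -> float:
    """Shortest-path distance in metres along network edges."""
    n = net.n_points
    if not (0 <= a < n and 0 <= b < n):
        raise ParameterError(f"point id out of range: {a}, {b}")
    if a == b:
        return 0.0
    try:
        return float(nx.shortest_path_length(net.graph, int(a), int(b),
                                             weight="weight"))
    except nx.NetworkXNoPath as exc:  # impossible on a valid network
        raise ParameterError(f"points {a} and {b} are disconnected") from exc


def points_within(net: LandscapeNetwork, origin: int, radius: float):
    """All points with network distance <= ``radius`` from ``origin``.

    Returns ``(ids, distances)`` sorted by id; includes the origin at 0.
    """
    if radius < 0:
        raise ParameterError("radius must be >= 0")
    if not 0 <= origin < net.n_points:
        raise ParameterError(f"point id out of range: {origin}")
    dist = _csgraph_dijkstra(net._sparse(), directed=False,
                             indices=int(origin), limit=float(radius))
    ids = np.flatnonzero(dist <= radius)
    return ids, dist[ids]


def nearest_best_latrine(net: LandscapeNetwork, origin: int,
                         radius: float):
    """Highest-quality latrine point within ``radius`` of ``origin``.

    Quality (MEP) dominates; ties break by smaller network distance, then
    smaller id.  Returns ``None`` when no latrine-grade point is in range.
    """
    ids, dist = points_within(net, origin, radius)
    mask = net.is_latrine[ids]
    if not mask.any():
        return None
    ids, dist = ids[mask], dist[mask]
    mep = net.mep[ids]
    order = np.lexsort((ids, dist, -mep))
    return int(ids[order[0]])


# ----------------------------------------------------------------------
# Synthetic landscape generator
# ----------------------------------------------------------------------

def generate_synthetic_landscape(total_coast_km: float, corridor_km: float,
                                 study_fraction: float, spawn_fraction: float,
                                 mep_autocorrelation_range: float, seed: int,
                                 spawn_patch_km: float = 1.0,
                                 latrine_threshold: float = DEFAULT_LATRINE_THRESHOLD,
                                 ) -> LandscapeNetwork:
    """Generate a connected synthetic coastline-plus-corridor network.

    The coastline is a single chain of ``round(total_coast_km * 100)``
    points 10 m apart laid along a gently meandering planar curve.  Habitat
    quality is a spatially autocorrelated field: uniform noise smoothed with
    a Gaussian kernel whose standard deviation equals
    ``mep_autocorrelation_range`` (km), then min-max rescaled to [0, 1],
    which reproduces the patchy distribution of latrine-grade habitat.
    Spawning habitat covers ``spawn_fraction`` of coastline points in
    contiguous ~``spawn_patch_km`` patches.  The in-study-area flag marks a
    contiguous block of ``study_fraction`` of the coastline.  Corridors
    ("virtual lines", one per ~2 km of corridor budget) short-cut between
    coastline points 3-8 km apart; their points carry ``mep = 0`` and no
    spawning habitat.
    """
    if total_coast_km <= 0:
        raise ParameterError("total_coast_km must be > 0")
    if corridor_km < 0:
        raise ParameterError("corridor_km must be >= 0")
    for name, p in (("study_fraction", study_fraction),
                    ("spawn_fraction", spawn_fraction)):
        if not 0 < p <= 1:
            raise ParameterError(f"{name} must be in (0, 1], got {p}")
    if mep_autocorrelation_range <= 0:
        raise ParameterError("mep_autocorrelation_range must be > 0")

    rng = np.random.default_rng(int(seed))
    n_coast = int(round(total_coast_km * 100))

    # meandering planar layout (cosmetic; network distance is authoritative)
    t = np.arange(n_coast, dtype=np.float64)
    coords = np.column_stack([t * POINT_SPACING_M,
                              400.0 * np.sin(2 * np.pi * t / 2000.0)])

    sigma_pts = mep_autocorrelation_range * 1000.0 / POINT_SPACING_M
    raw = rng.uniform(size=n_coast)
    smooth = gaussian_filter1d(raw, sigma=sigma_pts, mode="nearest")
    lo, hi = smooth.min(), smooth.max()
    mep = (smooth - lo) / (hi - lo) if hi > lo else np.full(n_coast, 0.5)

    in_study = np.zeros(n_coast, dtype=bool)
    in_study[: int(round(study_fraction * n_coast))] = True

    spawn = np.zeros(n_coast, dtype=bool)
    n_target = int(round(spawn_fraction * n_coast))
    patch_pts = max(1, int(round(spawn_patch_km * 100)))
    n_patches = max(1, int(round(n_target / patch_pts)))
    gap = n_coast / n_patches
    for k in range(n_patches):
        length = min(patch_pts, n_target - int(spawn.sum()))
        if length <= 0:
            break
        lo_start = int(k * gap)
        hi_start = max(lo_start + 1, int((k + 1) * gap) - length)
        start = int(rng.integers(lo_start, hi_start))
        spawn[start:start + length] = True
    # top up/trim to hit the target within one point
    deficit = n_target - int(spawn.sum())
    if deficit > 0:
        free = np.flatnonzero(~spawn)
        spawn[free[:deficit]] = True

    edges = [(i, i + 1, POINT_SPACING_M) for i in range(n_coast - 1)]
    segments = [np.arange(n_coast, dtype=np.int64)]

    coords_all = [coords]
    n_total = n_coast
    virtual_counts = 0
    if corridor_km > 0:
        n_corr = max(1, int(round(corridor_km / 2.0)))
        # distribute exactly round(corridor_km * 100) virtual points
        total_virtual = max(n_corr, int(round(corridor_km * 100)))
        base, extra = divmod(total_virtual, n_corr)
        for k in range(n_corr):
            p = base + (1 if k < extra else 0)
            span = int(rng.integers(300, 801))  # 3-8 km along-coast shortcut
            u = int(rng.integers(0, max(1, n_coast - span)))
            v = min(n_coast - 1, u + span)
            interior = np.linspace(coords[u], coords[v], p + 2)[1:-1]
            ids = np.arange(n_total, n_total + p, dtype=np.int64)
            chain = [u, *ids.tolist(), v]
            for a, b in zip(chain[:-1], chain[1:]):
                edges.append((int(a), int(b), POINT_SPACING_M))
            segments.append(np.array(chain, dtype=np.int64))
            coords_all.append(interior)
            n_total += p
            virtual_counts += p

    coords_full = np.vstack(coords_all)
    pad = lambda arr, fill: np.concatenate(
        [arr, np.full(virtual_counts, fill, dtype=arr.dtype)])
    net = LandscapeNetwork(
        coords=coords_full,
        mep=pad(mep, 0.0),
        radial_scale=np.ones(n_total),
        spawn_habitat=pad(spawn, False),
        in_study_area=pad(in_study, False),
        on_virtual_line=np.concatenate(
            [np.zeros(n_coast, dtype=bool), np.ones(virtual_counts, dtype=bool)]),
        edges=edges,
        latrine_threshold=latrine_threshold,
        segments=segments,
    )
    return net


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

_POINT_FIELDS = ("mep", "radial_scale", "spawn_habitat",
                 "in_study_area", "on_virtual_line")


def write_network(net: LandscapeNetwork, path: str,
                  format: str = "geojson") -> None:
    """Write a network to disk; ``read_network`` round-trips every field."""
    if format == "geojson":
        features = []
        for seg in net.segments:
            seg = np.asarray(seg)
            props = {"ids": [int(i) for i in seg]}
            for f in _POINT_FIELDS:
                arr = getattr(net, f)[seg]
                props[f] = [bool(x) if arr.dtype == bool else float(x)
                            for x in arr]
            lengths = [float(_edge_len(net, a, b))
                       for a, b in zip(seg[:-1], seg[1:])]
            props["edge_lengths_m"] = lengths
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [[float(x), float(y)]
                                             for x, y in net.coords[seg]]},
                "properties": props,
            })
        doc = {"type": "FeatureCollection",
               "latrine_threshold": net.latrine_threshold,
               "n_points": net.n_points,
               "features": features}
        with open(path, "w") as fh:
            json.dump(doc, fh)
    elif format == "node-edge-csv":
        os.makedirs(path, exist_ok=True)
        import pandas as pd
        nodes = pd.DataFrame({
            "id": np.arange(net.n_points),
            "x": net.coords[:, 0], "y": net.coords[:, 1],
            "mep": net.mep, "radial_scale": net.radial_scale,
            "spawn_habitat": net.spawn_habitat.astype(int),
            "in_study_area": net.in_study_area.astype(int),
            "on_virtual_line": net.on_virtual_line.astype(int)})
        # %.17g keeps the round trip bit-exact for float64 fields
        nodes.to_csv(os.path.join(path, "nodes.csv"), index=False,
                     float_format="%.17g")
        edges = pd.DataFrame({"from_id": net.edge_index[:, 0],
                              "to_id": net.edge_index[:, 1],
                              "length_m": net.edge_length})
        edges.to_csv(os.path.join(path, "edges.csv"), index=False,
                     float_format="%.17g")
        with open(os.path.join(path, "meta.json"), "w") as fh:
            json.dump({"latrine_threshold": net.latrine_threshold}, fh)
    else:
        raise ParameterError(f"unknown format {format!r}")


def _edge_len(net, a, b):
    key = (min(int(a), int(b)), max(int(a), int(b)))
    if not hasattr(net, "_elen_lookup"):
        net._elen_lookup = {(min(int(u), int(v)), max(int(u), int(v))): w
                            for (u, v), w in zip(net.edge_index,
                                                 net.edge_length)}
    return net._elen_lookup[key]


def read_network(path: str, format: str = "geojson") -> LandscapeNetwork:
    """Read a network written by :func:`write_network`."""
    if format == "geojson":
        with open(path) as fh:
            try:
                doc = json.load(fh)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        if doc.get("type") != "FeatureCollection":
            raise FormatError(f"{path}: expected a FeatureCollection")
        n = int(doc.get("n_points", 0))
        fields = {f: np.zeros(n, dtype=(bool if f != "mep"
                                        and f != "radial_scale" else float))
                  for f in _POINT_FIELDS}
        coords = np.zeros((n, 2))
        filled = np.zeros(n, dtype=bool)
        edges = []
        segments = []
        for fi, feat in enumerate(doc.get("features", [])):
            props = feat.get("properties", {})
            geom = feat.get("geometry", {})
            if "ids" not in props:
                raise FormatError(f"{path}: feature {fi} missing 'ids'")
            ids = np.asarray(props["ids"], dtype=np.int64)
            for f in _POINT_FIELDS:
                if f not in props:
                    raise FormatError(
                        f"{path}: feature {fi} missing property {f!r}")
                fields[f][ids] = np.asarray(props[f])
            coords[ids] = np.asarray(geom.get("coordinates"), dtype=float)
            filled[ids] = True
            lengths = props.get("edge_lengths_m",
                                [POINT_SPACING_M] * (len(ids) - 1))
            for a, b, w in zip(ids[:-1], ids[1:], lengths):
                edges.append((int(a), int(b), float(w)))
            segments.append(ids)
        if not filled.all():
            raise FormatError(f"{path}: {int((~filled).sum())} point ids "
                              "never appear in any feature")
        # drop duplicate edges from shared segment endpoints
        seen, uniq = set(), []
        for a, b, w in edges:
            key = (min(a, b), max(a, b))
            if key not in seen:
                seen.add(key)
                uniq.append((a, b, w))
        return LandscapeNetwork(
            coords=coords, edges=uniq,
            latrine_threshold=float(doc.get("latrine_threshold",
                                            DEFAULT_LATRINE_THRESHOLD)),
            segments=segments,
            **{f: fields[f] for f in _POINT_FIELDS})
    elif format == "node-edge-csv":
        import pandas as pd
        try:
            nodes = pd.read_csv(os.path.join(path, "nodes.csv"),
                                float_precision="round_trip")
            edges = pd.read_csv(os.path.join(path, "edges.csv"),
                                float_precision="round_trip")
        except FileNotFoundError as exc:
            raise FormatError(str(exc)) from exc
        required = {"id", "x", "y", *_POINT_FIELDS}
        missing = required - set(nodes.columns)
        if missing:
            raise FormatError(f"nodes.csv missing columns {sorted(missing)}")
        nodes = nodes.sort_values("id")
        if not np.array_equal(nodes["id"].to_numpy(),
                              np.arange(len(nodes))):
            raise FormatError("nodes.csv ids must be 0-based and contiguous")
        thr = DEFAULT_LATRINE_THRESHOLD
        meta_path = os.path.join(path, "meta.json")
        if os.path.exists(meta_path):
            with open(meta_path) as fh:
                thr = float(json.load(fh).get("latrine_threshold", thr))
        return LandscapeNetwork(
            coords=np.column_stack([nodes["x"], nodes["y"]]),
            mep=nodes["mep"].to_numpy(float),
            radial_scale=nodes["radial_scale"].to_numpy(float),
            spawn_habitat=nodes["spawn_habitat"].to_numpy().astype(bool),
            in_study_area=nodes["in_study_area"].to_numpy().astype(bool),
            on_virtual_line=nodes["on_virtual_line"].to_numpy().astype(bool),
            edges=list(zip(edges["from_id"], edges["to_id"],
                           edges["length_m"])),
            latrine_threshold=thr)
    raise ParameterError(f"unknown format {format!r}")
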