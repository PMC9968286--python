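"""Areas of open space (AOS): dissolving raw polygons, pseudo entry points,
per-address access lists and post-hoc typology queries.

Raw open-space polygons carry public-access, water and sport tags.
Adjacent or overlapping features dissolve into a single AOS whose public
geometry is the union of public features minus any restricted sub-areas
(e.g. a private golf course inside a park).  Access is modelled through
proxy entry points sampled every 20 m along the public boundary, retained
only where within 30 m (Euclidean) of the walkable network; an address's
access list records, for every AOS reachable within 3200 m, the minimum
network distance over that AOS's entry points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.ops import unary_union

from . import access as access_mod
from . import pednet
from .pednet import Anchor, PedNetwork

#: Entry-point sampling interval along AOS boundaries (metres).
DEFAULT_ENTRY_INTERVAL_M = 20.0
#: Maximum Euclidean gap between an entry point and the network (metres).
DEFAULT_MAX_NET_GAP_M = 30.0
#: Amenity co-location radius (metres).
AMENITY_COLOCATION_M = 100.0
#: Large public open space area threshold (hectares) and access distance (m).
LARGE_POS_HA = 1.5
POS_THRESHOLD_M = 400.0


@dataclass
class AreaOfOpenSpace:
    aos_id: str
    geometry: shapely.Geometry
    public_geometry: shapely.Geometry
    water_geometry: shapely.Geometry
    co_located: list[str]
    has_sport_facility: bool

    @property
    def public_area_ha(self) -> float:
        return self.public_geometry.area / 10_000.0


@dataclass
class EntryPointSet:
    aos_id: str
    points: list[tuple[str, Point]]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AosAccessList:
    """Per-address (aos_id, network distance m) entries, sorted ascending,
    one per AOS reachable within the cutoff."""

    address_id: object
    entries: list[tuple[str, int]]
    cutoff_m: float = access_mod.DEFAULT_CUTOFF_M


def build_aos(features, amenities=None) -> list[AreaOfOpenSpace]:
    """Dissolve raw tagged polygons into areas of open space.

    ``features``: DataFrame with columns ``feature_id, public, water, sport,
    geometry`` (or an iterable of such tuples).  ``amenities``: DataFrame
    with ``name, geometry`` point rows; amenities within 100 m of an AOS are
    attached as co-located.  Invalid geometries are skipped with a warning.
    """
    if isinstance(features, pd.DataFrame):
        feats = list(
            features[["feature_id", "public", "water", "sport", "geometry"]]
            .itertuples(index=False, name=None)
        )
    else:
        feats = list(features)
    clean = []
    for fid, public, water, sport, geom in feats:
        if geom is None or geom.is_empty or not geom.is_valid:
            warnings.warn(f"skipping open-space feature {fid!r}: invalid geometry")
            continue
        clean.append((fid, bool(public), bool(water), bool(sport), geom))
    clean.sort(key=lambda f: str(f[0]))

    # union-find on spatial connectivity (intersects covers touching/overlap)
    n = len(clean)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    geoms = np.array([f[4] for f in clean], dtype=object)
    if n:
        tree = shapely.STRtree(geoms)
        for i in range(n):
            for j in tree.query(geoms[i], predicate="intersects"):
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    amen: list[tuple[str, Point]] = []
    if amenities is not None:
        if isinstance(amenities, pd.DataFrame):
            amen = list(zip(amenities["name"], amenities["geometry"]))
        else:
            amen = list(amenities)

    out: list[AreaOfOpenSpace] = []
    for k, root in enumerate(sorted(groups)):
        members = [clean[i] for i in groups[root]]
        overall = unary_union([m[4] for m in members])
        public_parts = [m[4] for m in members if m[1]]
        restricted = [m[4] for m in members if not m[1]]
        public = unary_union(public_parts) if public_parts else shapely.Polygon()
        if restricted:
            public = public.difference(unary_union(restricted))
        water_parts = [m[4] for m in members if m[2]]
        water = unary_union(water_parts) if water_parts else shapely.Polygon()
        co = sorted(
            name for name, pt in amen
            if shapely.distance(overall, pt) <= AMENITY_COLOCATION_M
        )
        out.append(
            AreaOfOpenSpace(
                aos_id=f"AOS{k:04d}",
                geometry=overall,
                public_geometry=public,
                water_geometry=water,
                co_located=co,
                has_sport_facility=any(m[3] for m in members),
            )
        )
    return out


def entry_points(
    aos: AreaOfOpenSpace,
    net: PedNetwork,
    interval_m: float = DEFAULT_ENTRY_INTERVAL_M,
    max_net_gap_m: float = DEFAULT_MAX_NET_GAP_M,
) -> EntryPointSet:
    """Sample the public boundary at arc-length multiples of ``interval_m``
    (starting at the ring start vertex; no duplicate at closure) and keep
    samples within ``max_net_gap_m`` Euclidean of any network edge."""
    geom = aos.public_geometry
    if geom.is_empty:
        return EntryPointSet(aos.aos_id, [])
    polys = list(geom.geoms) if geom.geom_type == "MultiPolygon" else [geom]
    _, edge_geoms = net.edge_geometries()
    pts: list[tuple[str, Point]] = []
    k = 0
    for poly in polys:
        ring = poly.exterior
        for s in np.arange(0.0, ring.length, interval_m):
            pt = ring.interpolate(float(s))
            if len(edge_geoms) and shapely.distance(edge_geoms, pt).min() <= max_net_gap_m:
                pts.append((f"{aos.aos_id}_EP{k:04d}", pt))
            k += 1
    return EntryPointSet(aos.aos_id, pts)


def aos_access(
    anchors: dict,
    entry_sets: list[EntryPointSet],
    net: PedNetwork,
    cutoff_m: float = access_mod.DEFAULT_CUTOFF_M,
) -> dict:
    """Per-address access list: for each AOS the minimum network distance
    over its entry points, kept when within the cutoff.  An address inside
    an AOS still routes to a boundary entry point (no zero-inside shortcut).
    """
    ep_anchors: dict = {}
    ep_aos: dict = {}
    for es in entry_sets:
        if not es.points:
            continue
        snapped = pednet.snap_points(es.points, net)
        for ep_id, anc in snapped.items():
            ep_anchors[ep_id] = anc
            ep_aos[ep_id] = es.aos_id
    arrays = access_mod.od_distances(
        anchors, ep_anchors, net, cutoff_m=cutoff_m, category="aos_entry",
        keep_ids=True,
    )
    out: dict = {}
    for aid, arr in arrays.items():
        best: dict[str, int] = {}
        for d, ep_id in zip(arr.distances, arr.ids or []):
            aos_id = ep_aos[ep_id]
            if aos_id not in best or d < best[aos_id]:
                best[aos_id] = d
        entries = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))
        out[aid] = AosAccessList(aid, [(a, d) for a, d in entries], cutoff_m)
    return out


def query_pos(
    access_list: AosAccessList,
    aos_by_id: dict,
    min_area_ha: float | None = None,
    max_area_ha: float | None = None,
    require_amenity: str | None = None,
    require_sport: bool = False,
) -> int | None:
    """Distance to the closest AOS satisfying every filter clause.

    Area bounds follow the published typology notation: strictly greater
    than ``min_area_ha`` and at most (inclusive) ``max_area_ha``.  Returns
    null when no AOS qualifies.
    """
    if min_area_ha is not None and max_area_ha is not None and min_area_ha > max_area_ha:
        raise ValueError("min_area_ha exceeds max_area_ha")
    for aos_id, dist in access_list.entries:
        aos = aos_by_id[aos_id]
        if min_area_ha is not None and not aos.public_area_ha > min_area_ha:
            continue
        if max_area_ha is not None and not aos.public_area_ha <= max_area_ha:
            continue
        if require_amenity is not None and require_amenity not in aos.co_located:
            continue
        if require_sport and not aos.has_sport_facility:
            continue
        return dist
    return None


def pos_indicator(distance_m: float | None, threshold_m: float = POS_THRESHOLD_M,
                  mode: str = "soft", k: float = access_mod.DEFAULT_SOFT_K) -> float:
    """Access score for public open space at the 400 m threshold."""
    return access_mod.score(distance_m, threshold_m, mode=mode, k=k)
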