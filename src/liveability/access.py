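"""Origin-destination accessibility along the pedestrian network.

Per address and destination category the full array of network distances to
destinations within 3200 m is recorded (a value relevant to walkability
policy: twice the 1600 m walkable catchment) together with the overall
closest destination regardless of cutoff.  Distances are stored as integer
metres (rounded half up).  Where a destination concept is covered by two
independent sources (e.g. supermarkets from a mapped and a web-scraped
dataset) the closest estimates are pooled by row-wise minimum; count-within
queries are only permitted on single-source arrays so that no destination is
double counted.

Access to a destination is scored out of 1 against a distance threshold T,
either with a hard cutoff (1 if d <= T else 0) or the soft logistic
threshold  1 / (1 + exp(k (d - T) / T))  which equals 0.5 at d = T and
decays smoothly (k = 5 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from . import pednet
from .pednet import Anchor, PedNetwork

#: Destination array cutoff (metres).
DEFAULT_CUTOFF_M = 3200.0
#: Public transport stop array cutoff (metres).
STOP_CUTOFF_M = 800.0
#: Soft-threshold steepness.
DEFAULT_SOFT_K = 5.0


class PooledArrayError(ValueError):
    """Raised when a count-within query is attempted on a pooled array."""


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class DistanceArray:
    """Sorted network distances (integer metres) within a cutoff, plus the
    closest destination regardless of cutoff.  ``ids`` (when present) runs
    parallel to ``distances``."""

    address_id: object
    category: str
    distances: list[int]
    closest: int | None
    ids: list | None = None
    closest_id: object | None = None
    cutoff_m: float = DEFAULT_CUTOFF_M
    pooled: bool = False

    def __post_init__(self) -> None:
        if self.distances != sorted(self.distances):
            raise ValueError("distance array must be sorted ascending")
        if self.distances:
            if self.closest is None or self.closest > self.distances[0]:
                raise ValueError("closest must not exceed the first array element")


def od_distance_tables(
    anchors: dict,
    destination_groups: dict,
    net: PedNetwork,
    cutoffs: dict | None = None,
    default_cutoff_m: float = DEFAULT_CUTOFF_M,
    keep_ids: bool = False,
) -> dict:
    """Distance arrays for several destination categories in one pass.

    ``destination_groups`` maps category -> {destination id -> Anchor};
    destination ids may repeat across categories.  One shortest-path tree is
    grown per address over a single augmented graph carrying every anchor,
    so per-address cost is independent of the number of categories.
    Returns {category: {address id: DistanceArray}}.
    """
    cutoffs = cutoffs or {}
    # key destination anchors by (category, id) so ids never collide
    combined: dict = {}
    for cat, group in destination_groups.items():
        for did, anc in group.items():
            key = (cat, did)
            combined[key] = Anchor(key, anc.edge_id, anc.offset_m, anc.snap_m, anc.point)
    aug = pednet.insert_anchors(
        net, list(anchors.values()) + list(combined.values())
    )
    out: dict = {cat: {} for cat in destination_groups}
    for aid, anchor in anchors.items():
        dist = nx.single_source_dijkstra_path_length(
            aug, pednet.anchor_node(aid), weight="length"
        )
        for cat, group in destination_groups.items():
            cutoff = cutoffs.get(cat, default_cutoff_m)
            pairs = sorted(
                (round_half_up(dist[pednet.anchor_node((cat, did))]), str(did), did)
                for did in group
                if pednet.anchor_node((cat, did)) in dist
            )
            within = [(d, did) for d, _, did in pairs if d <= cutoff]
            out[cat][aid] = DistanceArray(
                address_id=aid,
                category=cat,
                distances=[d for d, _ in within],
                closest=pairs[0][0] if pairs else None,
                ids=[did for _, did in within] if keep_ids else None,
                closest_id=pairs[0][2] if (keep_ids and pairs) else None,
                cutoff_m=cutoff,
            )
    return out


def od_distances(
    anchors: dict,
    destinations: dict,
    net: PedNetwork,
    cutoff_m: float = DEFAULT_CUTOFF_M,
    category: str = "",
    keep_ids: bool = False,
) -> dict:
    """Exact shortest-path distance arrays, one per address.

    ``anchors`` and ``destinations`` map ids to :class:`Anchor` snapped by
    the same rule.  The closest destination is computed without cutoff;
    addresses with no reachable destination get an empty array and a null
    closest.
    """
    tables = od_distance_tables(
        anchors,
        {category: destinations},
        net,
        cutoffs={category: cutoff_m},
        keep_ids=keep_ids,
    )
    return tables[category]


def pool_closest(a: int | None, b: int | None) -> int | None:
    """Best closest-distance estimate across two sources for the same
    concept: the row-wise minimum, treating null as unreachable."""
    if a is None:
        return b
    if b is None:
        return a
    return min(a, b)


def count_within(arr: DistanceArray, d_m: float) -> int:
    """Number of destinations within ``d_m`` (inclusive).  Only meaningful
    for single-source arrays: pooled arrays are rejected to rule out double
    counting."""
    if arr.pooled:
        raise PooledArrayError(
            "count-within queries require a single-source distance array"
        )
    if d_m > arr.cutoff_m:
        raise ValueError(f"query distance {d_m} exceeds array cutoff {arr.cutoff_m}")
    return sum(1 for d in arr.distances if d <= d_m)


def soft_score(d_m: float | None, threshold_m: float, k: float = DEFAULT_SOFT_K) -> float:
    """Soft-threshold access score: 1 / (1 + exp(k (d - T) / T)).

    Equals 0.5 at the threshold, approaches 1 for nearby destinations and 0
    for remote ones; a null (unreachable) distance scores 0.
    """
    if threshold_m <= 0:
        raise ValueError("threshold_m must be positive")
    if d_m is None:
        return 0.0
    x = k * (d_m - threshold_m) / threshold_m
    if x > 700:  # avoid overflow; score is numerically 0
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


def hard_score(d_m: float | None, threshold_m: float) -> float:
    """Binary access score: 1 if the destination is within the threshold
    (inclusive), else 0; a null distance scores 0."""
    if threshold_m <= 0:
        raise ValueError("threshold_m must be positive")
    if d_m is None:
        return 0.0
    return 1.0 if d_m <= threshold_m else 0.0


def score(d_m: float | None, threshold_m: float, mode: str = "soft",
          k: float = DEFAULT_SOFT_K) -> float:
    if mode == "soft":
        return soft_score(d_m, threshold_m, k)
    if mode == "hard":
        return hard_score(d_m, threshold_m)
    raise ValueError(f"unknown scoring mode {mode!r}")
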