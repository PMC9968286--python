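"""End-to-end indicator pipeline for a (synthetic) city.

Runs the full sequence: network build and intersection consolidation,
address and destination snapping, walkable catchments with density and
connectivity, origin-destination distance arrays (3200 m; 800 m for
transit stops), supermarket min-pooling across sources, open-space entry
points and access, transit headways, per-address sub-indicators, composite
walkability, exclusion flags with tally, the Urban Liveability Index at
both scopes, and mesh-block through city aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import access as access_mod
from . import aggregate_export as agg
from . import indicators as ind
from . import open_space as aos_mod
from . import pednet, transit, uli
from .synthetic_city import SyntheticCity

#: Address-level indicator columns carried through aggregation.
AGGREGATE_COLUMNS = (
    list(uli.ULI_COLUMNS)
    + [
        "daily_living_access_1600m",
        "social_infrastructure_mix",
        "walkability_city",
        "walkability_national",
        "uli_city",
        "uli_national",
        "dist_m_supermarket_pooled",
        "pct_supermarket_1000m",
        "pct_large_pos_400m",
    ]
)


@dataclass
class PipelineResult:
    addresses: pd.DataFrame
    tally: agg.ExclusionTally
    meshblock_summary: pd.DataFrame
    area_summaries: dict[str, pd.DataFrame]
    headways: dict
    catchments: dict
    intersections: pednet.IntersectionSet
    net: pednet.PedNetwork
    aos: list
    aos_lists: dict
    distance_arrays: dict


def _destination_groups(city: SyntheticCity, net: pednet.PedNetwork):
    """Snap destinations into per-member anchor groups.

    Members map to generator categories directly, except: supermarkets come
    from two sources (pooled downstream), and the early-years members use
    only childcare points meeting the quality requirement.
    """
    dest = city.destinations
    member_filters = {}
    for members in ind.CATEGORY_MEMBERS.values():
        for member in members:
            member_filters[member] = (member, None, None)
    member_filters["supermarket"] = ("supermarket", "osm", None)
    member_filters["supermarket_chain"] = ("supermarket", "chain", None)
    member_filters["childcare_quality"] = ("childcare", None, True)
    member_filters["childcare_oshc_quality"] = ("childcare_oshc", None, True)

    groups = {}
    for member, (cat, source, quality) in member_filters.items():
        sel = dest["category"] == cat
        if source is not None:
            sel &= dest["source"] == source
        if quality is not None:
            sel &= dest["meets_quality"] == quality
        pts = list(zip(dest.loc[sel, "dest_id"], dest.loc[sel, "geometry"]))
        groups[member] = pednet.snap_points(pts, net) if pts else {}
    return groups


def run_pipeline(
    city: SyntheticCity,
    mode: str = "soft",
    k: float = access_mod.DEFAULT_SOFT_K,
    consolidation_tolerance_m: float = pednet.DEFAULT_INTERSECTION_TOLERANCE_M,
    catchment_range_m: float = pednet.DEFAULT_CATCHMENT_RANGE_M,
    catchment_buffer_m: float = pednet.DEFAULT_CATCHMENT_BUFFER_M,
) -> PipelineResult:
    net = pednet.build_network(city.nodes, city.edges)
    intersections = pednet.consolidate_intersections(net, consolidation_tolerance_m)

    addr_ids = list(city.addresses["address_id"])
    addr_anchors = pednet.snap_points(
        list(zip(city.addresses["address_id"], city.addresses["geometry"])), net
    )

    # walkable catchments, density, connectivity
    catchments = {
        aid: pednet.network_catchment(
            net, addr_anchors[aid], catchment_range_m, catchment_buffer_m
        )
        for aid in addr_ids
    }
    density = {
        aid: pednet.dwelling_density(catchments[aid], city.meshblocks)
        for aid in addr_ids
    }
    connectivity = {
        aid: pednet.street_connectivity(catchments[aid], intersections)
        for aid in addr_ids
    }

    # destination distance arrays (one Dijkstra pass per address)
    groups = _destination_groups(city, net)
    stop_anchors = pednet.snap_points(
        list(zip(city.stops["stop_id"], city.stops["geometry"])), net
    )
    groups["pt_stop"] = stop_anchors
    cutoffs = {"pt_stop": access_mod.STOP_CUTOFF_M}
    arrays = access_mod.od_distance_tables(
        addr_anchors, groups, net, cutoffs=cutoffs, keep_ids=True
    )

    # open space
    aos_list = aos_mod.build_aos(city.open_space_features, city.amenities)
    entry_sets = [aos_mod.entry_points(a, net) for a in aos_list]
    aos_lists = aos_mod.aos_access(addr_anchors, entry_sets, net)
    aos_by_id = {a.aos_id: a for a in aos_list}

    # transit headways
    headways = transit.stop_headways(
        city.stop_times,
        modes=dict(zip(city.stops["stop_id"], city.stops["mode"])),
    )

    mb = city.meshblocks.set_index("mb_code")
    rows = []
    for aid in addr_ids:
        mb_code = city.addresses.set_index("address_id").loc[aid, "mb_code"]
        closest = {m: arrays[m][aid].closest for m in groups}
        pooled_supermarket = access_mod.pool_closest(
            closest["supermarket"], closest["supermarket_chain"]
        )
        member_dist = dict(closest)
        member_dist["supermarket"] = pooled_supermarket

        rec = {"address_id": aid, "mb_code": mb_code}
        for level in ("sa1", "sa2", "sa3", "sa4", "suburb", "lga", "city"):
            rec[level] = mb.loc[mb_code, level]
        for m in groups:
            rec[f"dist_m_{m}"] = closest[m]
        rec["dist_m_supermarket_pooled"] = pooled_supermarket

        for cat, members in ind.CATEGORY_MEMBERS.items():
            rec[cat] = ind.category_score(
                {m: member_dist[m] for m in members}, cat, mode=mode, k=k
            )
        rec["daily_living_access_1600m"] = ind.daily_living(
            pooled_supermarket, closest["pt_stop"], closest["convenience_store"],
            mode=mode, k=k,
        )
        rec["social_infrastructure_mix"] = ind.social_infrastructure_mix(
            {m: member_dist[m] for m in ind.SOCIAL_INFRA_MEMBERS}, mode=mode, k=k
        )
        rec["li_pt_regular_400m"] = transit.pt_regular_access(
            arrays["pt_stop"][aid], headways, mode=mode, k=k
        )
        pos_dist = aos_mod.query_pos(
            aos_lists[aid], aos_by_id, min_area_ha=aos_mod.LARGE_POS_HA
        )
        rec["dist_m_large_pos"] = pos_dist
        rec["li_public_os_large_400m"] = aos_mod.pos_indicator(pos_dist, mode=mode, k=k)
        rec["li_dwelling_density_1600m"] = density[aid]
        rec["li_street_connectivity_1600m"] = connectivity[aid]
        linked = ind.link_sa1(rec["sa1"], city.sa1_covariates)
        linked.pop("no_index")  # recomputed by apply_exclusions below
        rec.update(linked)
        # hard-threshold splits for percent-meeting aggregation
        rec["pct_supermarket_1000m"] = 100.0 * access_mod.hard_score(pooled_supermarket, 1000)
        rec["pct_large_pos_400m"] = 100.0 * access_mod.hard_score(pos_dist, 400)
        rows.append(rec)
    addresses = pd.DataFrame(rows)

    flags, tally = agg.apply_exclusions(
        city.addresses, city.meshblocks, city.sa1_covariates, catchments
    )
    addresses = pd.concat([addresses, flags], axis=1)

    included = addresses["included"]
    for scope in ("city", "national"):
        addresses[f"walkability_{scope}"] = np.nan
        addresses.loc[included, f"walkability_{scope}"] = ind.walkability(
            addresses[included], scope=scope
        )
        addresses[f"uli_{scope}"] = np.nan
        addresses.loc[included, f"uli_{scope}"] = uli.compute_uli(
            addresses[included], scope=scope
        )

    mb_summary = agg.aggregate_meshblock(
        addresses, AGGREGATE_COLUMNS, city.meshblocks
    )
    area_summaries = {
        level: agg.aggregate_area(mb_summary, level, AGGREGATE_COLUMNS)
        for level in ("sa1", "sa2", "sa3", "sa4", "suburb", "lga", "city")
    }

    return PipelineResult(
        addresses=addresses,
        tally=tally,
        meshblock_summary=mb_summary,
        area_summaries=area_summaries,
        headways=headways,
        catchments=catchments,
        intersections=intersections,
        net=net,
        aos=aos_list,
        aos_lists=aos_lists,
        distance_arrays=arrays,
    )


def export_results(result: PipelineResult, city: SyntheticCity, directory) -> list[str]:
    """Write the published file shapes for a pipeline run."""
    closest_cols = ["address_id"] + sorted(
        c for c in result.addresses.columns if c.startswith("dist_m_")
    )
    datasets = {
        "address_indicators": result.addresses.drop(columns=[], errors="ignore"),
        "distance_closest": result.addresses[closest_cols],
        "distance_arrays.psv": agg.format_distance_arrays(result.distance_arrays),
        "stop_headways": transit.headway_table(result.headways, city.stops),
        "aos": agg.format_aos_table(result.aos),
        "od_aos.tsv": agg.format_od_aos(result.aos_lists),
        "meshblock_summary": result.meshblock_summary,
        "exclusion_tally": result.tally.table(),
    }
    for level, df in result.area_summaries.items():
        datasets[f"area_{level}"] = df
    return agg.export(datasets, directory)
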