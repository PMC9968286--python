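"""Deterministic synthetic city generator.

Emulates the input data model of a national liveability analysis so that
every pipeline stage is testable without any external download: a planar
grid street network with metre coordinates (a local projected frame; no
geodesy), mesh-block polygons (the grid cells, carrying 30-60 dwellings
each) nested exactly into SA1..SA4 / suburb / LGA / city linkage codes by
recursive 2x2 unions, address points inside mesh blocks, categorised
destination points (including supermarkets from two independent sources and
quality-flagged childcare), tagged open-space polygons with amenities, a
GTFS-like weekday/weekend departure schedule over a date window, and
SA1-level covariates.

Pathological features are generated on purpose so the exclusion rules can
be exercised: a small address cluster on a subgraph disconnected from (and
more than 3200 m away from) the main network, a known set of zero-dwelling
mesh blocks, a set of non-urban mesh blocks, and one SA1 without the area
disadvantage index.  Weekend service runs at three times the weekday
headway so that incorrect day filtering is detectable.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, box

from .indicators import CATEGORY_MEMBERS

__all__ = [
    "CityConfig",
    "SyntheticCity",
    "ConfigurationError",
    "generate_city",
    "generate_schedule",
    "write_fixtures",
    "city_fingerprint",
    "FIXTURE_MANIFEST",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


def _default_destination_densities() -> dict[str, int]:
    counts = {}
    for cat, members in CATEGORY_MEMBERS.items():
        for member in members:
            counts[member] = 6
    # childcare is generated with a quality flag; the quality-filtered
    # member sets are derived downstream
    del counts["childcare_quality"], counts["childcare_oshc_quality"]
    counts["childcare"] = 8
    counts["childcare_oshc"] = 6
    counts["supermarket_chain"] = 4  # second, independently sourced set
    counts["convenience_store"] = 10
    counts["cinema_theatre"] = 3
    counts["museum_art_gallery"] = 3
    return counts


@dataclass
class CityConfig:
    seed: int = 0
    grid_rows: int = 12
    grid_cols: int = 12
    cell_size_m: float = 200.0
    n_addresses: int = 400
    dwellings_per_meshblock_range: tuple[int, int] = (30, 60)
    destination_densities: dict[str, int] = field(
        default_factory=_default_destination_densities
    )
    open_space_fraction: float = 0.12
    transit_headway_minutes: dict[str, float] = field(
        default_factory=lambda: {"bus": 15.0, "tram": 25.0, "train": 45.0}
    )
    date_window: tuple[dt.date, dt.date] = (dt.date(2019, 10, 8), dt.date(2019, 12, 5))
    disconnected_component_fraction: float = 0.02
    #: share of each destination category placed inside the designated
    #: high-access district (the top-left ninth of the grid); the remainder
    #: is spread uniformly
    district_destination_share: float = 0.5
    city_name: str = "synthville"

    def validate(self) -> None:
        for name in ("grid_rows", "grid_cols", "n_addresses"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        if self.cell_size_m <= 0:
            raise ConfigurationError("cell_size_m must be positive")
        lo, hi = self.dwellings_per_meshblock_range
        if lo < 0 or hi < lo:
            raise ConfigurationError("dwellings_per_meshblock_range must be 0 <= lo <= hi")
        if not 0 <= self.open_space_fraction <= 1:
            raise ConfigurationError("open_space_fraction must lie in [0, 1]")
        if not 0 <= self.disconnected_component_fraction <= 1:
            raise ConfigurationError(
                "disconnected_component_fraction must lie in [0, 1]"
            )
        if not 0 <= self.district_destination_share <= 1:
            raise ConfigurationError("district_destination_share must lie in [0, 1]")
        start, end = self.date_window
        if start > end:
            raise ConfigurationError("date_window start must not exceed end")
        for route, hw in self.transit_headway_minutes.items():
            if hw <= 0:
                raise ConfigurationError(
                    f"transit_headway_minutes[{route!r}] must be positive"
                )
        for cat, n in self.destination_densities.items():
            if n < 0:
                raise ConfigurationError(
                    f"destination_densities[{cat!r}] must be non-negative"
                )


@dataclass
class SyntheticCity:
    """In-memory city: plain DataFrames with shapely geometry columns."""

    nodes: pd.DataFrame
    edges: pd.DataFrame
    addresses: pd.DataFrame
    meshblocks: pd.DataFrame
    destinations: pd.DataFrame
    open_space_features: pd.DataFrame
    amenities: pd.DataFrame
    stops: pd.DataFrame
    stop_times: pd.DataFrame
    sa1_covariates: pd.DataFrame
    total_dwellings: int
    district_mb_codes: list[str]
    zero_dwelling_mb_codes: list[str]
    disconnected_address_ids: list[str]


AREA_LEVELS = ["mb_code", "sa1", "sa2", "sa3", "sa4", "suburb", "lga", "city"]

#: Fixture file set written by :func:`write_fixtures`.
FIXTURE_MANIFEST = [
    "nodes.csv",
    "edges.csv",
    "addresses.csv",
    "meshblocks.csv",
    "destinations.csv",
    "open_space.csv",
    "amenities.csv",
    "stops.csv",
    "stop_times.csv",
    "calendar.csv",
    "sa1_covariates.csv",
    "city.json",
]


def _hierarchy_codes(r: int, c: int, city: str) -> dict[str, str]:
    """Linkage codes by recursive 2x2 unions of mesh-block grid cells, so the
    nesting is exact (each mesh block in one SA1, each SA1 in one SA2, ...)."""
    sa1 = f"SA1_{r // 2:02d}_{c // 2:02d}"
    sa2 = f"SA2_{r // 4:02d}_{c // 4:02d}"
    sa3 = f"SA3_{r // 8:02d}_{c // 8:02d}"
    sa4 = f"SA4_{r // 16:02d}_{c // 16:02d}"
    return {
        "sa1": sa1,
        "sa2": sa2,
        "sa3": sa3,
        "sa4": sa4,
        "suburb": f"SUB_{r // 4:02d}_{c // 4:02d}",
        "lga": f"LGA_{r // 8:02d}_{c // 8:02d}",
        "city": city,
    }


def generate_city(config: CityConfig) -> SyntheticCity:
    """Generate the city.  Identical configs give identical cities."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows, cols, cell = config.grid_rows, config.grid_cols, float(config.cell_size_m)
    width, height = cols * cell, rows * cell

    # --- street grid -------------------------------------------------------
    node_rows = []
    for r in range(rows + 1):
        for c in range(cols + 1):
            node_rows.append((f"N{r:03d}_{c:03d}", c * cell, r * cell))
    edge_rows = []
    for r in range(rows + 1):
        for c in range(cols + 1):
            if c < cols:
                geom = LineString([(c * cell, r * cell), ((c + 1) * cell, r * cell)])
                edge_rows.append(
                    (f"EH{r:03d}_{c:03d}", f"N{r:03d}_{c:03d}", f"N{r:03d}_{c + 1:03d}",
                     geom.length, geom)
                )
            if r < rows:
                geom = LineString([(c * cell, r * cell), (c * cell, (r + 1) * cell)])
                edge_rows.append(
                    (f"EV{r:03d}_{c:03d}", f"N{r:03d}_{c:03d}", f"N{r + 1:03d}_{c:03d}",
                     geom.length, geom)
                )

    # --- disconnected subgraph, > 3200 m beyond the main grid --------------
    n_remote_addr = (
        int(round(config.disconnected_component_fraction * config.n_addresses))
        if config.disconnected_component_fraction > 0
        else 0
    )
    remote_x = width + 4000.0
    if n_remote_addr > 0:
        node_rows.append(("NR000", remote_x, 0.0))
        node_rows.append(("NR001", remote_x + 400.0, 0.0))
        geom = LineString([(remote_x, 0.0), (remote_x + 400.0, 0.0)])
        edge_rows.append(("ER000", "NR000", "NR001", geom.length, geom))

    nodes = pd.DataFrame(node_rows, columns=["node_id", "x", "y"])
    edges = pd.DataFrame(
        edge_rows, columns=["edge_id", "from_node", "to_node", "length_m", "geometry"]
    )

    # --- mesh blocks and linkage hierarchy ---------------------------------
    d_lo, d_hi = config.dwellings_per_meshblock_range
    district_rows = max(1, rows // 3)
    district_cols = max(1, cols // 3)
    mb_rows = []
    idx = 0
    for r in range(rows):
        for c in range(cols):
            mb = f"MB{idx:05d}"
            in_district = r < district_rows and c < district_cols
            lo = (d_lo + d_hi) // 2 if in_district else d_lo
            dwellings = int(rng.integers(lo, d_hi + 1))
            persons = int(round(dwellings * rng.uniform(2.0, 3.0)))
            codes = _hierarchy_codes(r, c, config.city_name)
            mb_rows.append(
                {
                    "mb_code": mb,
                    "dwellings": dwellings,
                    "persons": persons,
                    **codes,
                    "urban": True,
                    "in_district": in_district,
                    "geometry": box(c * cell, r * cell, (c + 1) * cell, (r + 1) * cell),
                }
            )
            idx += 1
    # known pathological sets
    zero_dwelling = [mb_rows[0]["mb_code"], mb_rows[1]["mb_code"]]
    for row in mb_rows[:2]:
        row["dwellings"] = 0
        row["persons"] = 0
    for row in mb_rows[-2:]:
        row["urban"] = False
    if n_remote_addr > 0:
        mb_rows.append(
            {
                "mb_code": "MB_REMOTE",
                "dwellings": int(rng.integers(d_lo, d_hi + 1)),
                "persons": 0,
                "sa1": "SA1_REMOTE", "sa2": "SA2_REMOTE", "sa3": "SA3_REMOTE",
                "sa4": "SA4_REMOTE", "suburb": "SUB_REMOTE", "lga": "LGA_REMOTE",
                "city": config.city_name,
                "urban": True,
                "in_district": False,
                "geometry": box(remote_x - 200.0, -200.0, remote_x + 600.0, 200.0),
            }
        )
        mb_rows[-1]["persons"] = int(round(mb_rows[-1]["dwellings"] * 2.5))
    meshblocks = pd.DataFrame(mb_rows)
    district_mb = list(meshblocks.loc[meshblocks["in_district"], "mb_code"])
    total_dwellings = int(meshblocks["dwellings"].sum())

    # --- addresses ---------------------------------------------------------
    def point_in(geom, margin=0.05) -> Point:
        x0, y0, x1, y1 = geom.bounds
        return Point(
            x0 + (x1 - x0) * (margin + (1 - 2 * margin) * rng.random()),
            y0 + (y1 - y0) * (margin + (1 - 2 * margin) * rng.random()),
        )

    main_mb = meshblocks[meshblocks["mb_code"] != "MB_REMOTE"]
    weights = (main_mb["dwellings"] + 3.0).to_numpy(float)
    weights /= weights.sum()
    addr_rows = []
    disconnected_ids = []
    for i in range(config.n_addresses):
        if i < n_remote_addr:
            mb = meshblocks.iloc[-1]
            disconnected_ids.append(f"A{i:06d}")
        else:
            mb = main_mb.iloc[int(rng.choice(len(main_mb), p=weights))]
        addr_rows.append(
            {"address_id": f"A{i:06d}", "mb_code": mb["mb_code"],
             "geometry": point_in(mb["geometry"])}
        )
    addresses = pd.DataFrame(addr_rows)

    # --- destinations ------------------------------------------------------
    district_box = box(0.0, 0.0, district_cols * cell, district_rows * cell)
    dest_rows = []
    k = 0
    for category in sorted(config.destination_densities):
        count = config.destination_densities[category]
        for _ in range(count):
            in_district = rng.random() < config.district_destination_share
            target = district_box if in_district else box(0.0, 0.0, width, height)
            pt = point_in(target, margin=0.02)
            if category == "supermarket_chain":
                cat, source = "supermarket", "chain"
            else:
                cat, source = category, "osm"
            meets_quality = (
                bool(rng.random() < 0.7) if cat.startswith("childcare") else True
            )
            dest_rows.append(
                {"dest_id": f"D{k:05d}", "category": cat, "source": source,
                 "meets_quality": meets_quality, "geometry": pt}
            )
            k += 1
    destinations = pd.DataFrame(dest_rows)

    # --- open space --------------------------------------------------------
    os_rows, amenity_rows = [], []
    f = a = 0
    park_cells = [
        (r, c)
        for r in range(rows)
        for c in range(cols)
        if rng.random() < config.open_space_fraction
    ]
    for j, (r, c) in enumerate(park_cells):
        s = rng.uniform(0.35, 0.95)
        side = s * cell
        cx, cy = (c + 0.5) * cell, (r + 0.5) * cell
        base = box(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
        sport = bool(rng.random() < 0.3)
        if j == 0:
            # two abutting halves: exercises the dissolve step
            left = box(cx - side / 2, cy - side / 2, cx, cy + side / 2)
            right = box(cx, cy - side / 2, cx + side / 2, cy + side / 2)
            os_rows.append({"feature_id": f"OS{f:04d}", "public": True, "water": False,
                            "sport": sport, "geometry": left}); f += 1
            os_rows.append({"feature_id": f"OS{f:04d}", "public": True, "water": False,
                            "sport": False, "geometry": right}); f += 1
        else:
            os_rows.append({"feature_id": f"OS{f:04d}", "public": True, "water": False,
                            "sport": sport, "geometry": base}); f += 1
            if j == 1:
                # restricted sub-area (e.g. a private golf course)
                inner = box(cx - side / 4, cy - side / 4, cx + side / 4, cy + side / 4)
                os_rows.append({"feature_id": f"OS{f:04d}", "public": False,
                                "water": False, "sport": False, "geometry": inner})
                f += 1
            elif rng.random() < 0.25:
                w = side / 5
                water = box(cx - w, cy - w, cx + w, cy + w)
                os_rows.append({"feature_id": f"OS{f:04d}", "public": True,
                                "water": True, "sport": False, "geometry": water})
                f += 1
        if rng.random() < 0.4:
            amenity_rows.append(
                {"amenity_id": f"AM{a:04d}", "name": "public_toilet",
                 "geometry": Point(cx + side / 2 + 5.0, cy)}
            )
            a += 1
    open_space_features = pd.DataFrame(
        os_rows, columns=["feature_id", "public", "water", "sport", "geometry"]
    )
    amenities = pd.DataFrame(
        amenity_rows, columns=["amenity_id", "name", "geometry"]
    )

    # --- transit stops and schedule ----------------------------------------
    routes = sorted(config.transit_headway_minutes)
    stop_rows = []
    s_i = 0
    for j, route in enumerate(routes):
        row_idx = (rows * (j + 1)) // (len(routes) + 1)
        for c in range(0, cols + 1, 2):
            stop_rows.append(
                {"stop_id": f"S{s_i:04d}", "mode": route, "route": route,
                 "geometry": Point(c * cell, row_idx * cell)}
            )
            s_i += 1
    stops = pd.DataFrame(stop_rows, columns=["stop_id", "mode", "route", "geometry"])
    stop_times = generate_schedule(config, stops)

    # --- SA1 covariates ----------------------------------------------------
    sa1s = sorted(meshblocks["sa1"].unique())
    main_sa1s = [s for s in sa1s if s != "SA1_REMOTE"]
    no_index_sa1 = main_sa1s[-1]
    cov_rows = []
    for sa1 in sa1s:
        cov_rows.append(
            {
                "sa1": sa1,
                "pct_housing_stress": float(np.round(rng.uniform(5, 35), 4)),
                "pct_local_employment": float(np.round(rng.uniform(20, 80), 4)),
                "disadvantage_index": float(np.round(rng.normal(1000, 50), 4)),
                "has_index": sa1 != no_index_sa1,
            }
        )
    sa1_covariates = pd.DataFrame(cov_rows)

    return SyntheticCity(
        nodes=nodes,
        edges=edges,
        addresses=addresses,
        meshblocks=meshblocks,
        destinations=destinations,
        open_space_features=open_space_features,
        amenities=amenities,
        stops=stops,
        stop_times=stop_times,
        sa1_covariates=sa1_covariates,
        total_dwellings=total_dwellings,
        district_mb_codes=district_mb,
        zero_dwelling_mb_codes=zero_dwelling,
        disconnected_address_ids=disconnected_ids,
    )


def generate_schedule(config: CityConfig, stops: pd.DataFrame) -> pd.DataFrame:
    """Fixed-headway departure table over the configured date window.

    Weekday departures run at the route's configured headway from 07:00 to
    19:00 inclusive; weekend days are present but sparse (three times the
    weekday headway) so that incorrect day filtering is detectable.
    """
    start, end = config.date_window
    if start > end:
        raise ConfigurationError("date_window start must not exceed end")
    if stops.empty:
        raise ConfigurationError("stops must be non-empty")
    rows = []
    dates = pd.date_range(start, end, freq="D")
    for _, stop in stops.iterrows():
        headway = float(config.transit_headway_minutes[stop["route"]])
        if headway <= 0:
            raise ConfigurationError(
                f"transit_headway_minutes[{stop['route']!r}] must be positive"
            )
        for date in dates:
            h = headway if date.weekday() < 5 else headway * 3
            t = 7 * 60.0
            while t <= 19 * 60.0 + 1e-9:
                minutes = int(t)
                seconds = int(round((t - minutes) * 60))
                rows.append(
                    {
                        "stop_id": stop["stop_id"],
                        "service_date": date.date().isoformat(),
                        "departure_time": f"{minutes // 60:02d}:{minutes % 60:02d}:{seconds:02d}",
                    }
                )
                t += h
    return pd.DataFrame(rows, columns=["stop_id", "service_date", "departure_time"])


# ---------------------------------------------------------------------------
# Fixture serialisation

_GEOM_TABLES = {
    "nodes": None,
    "edges": "geometry",
    "addresses": "geometry",
    "meshblocks": "geometry",
    "destinations": "geometry",
    "open_space_features": "geometry",
    "amenities": "geometry",
    "stops": "geometry",
    "stop_times": None,
    "sa1_covariates": None,
}

_TABLE_FILES = {
    "nodes": "nodes.csv",
    "edges": "edges.csv",
    "addresses": "addresses.csv",
    "meshblocks": "meshblocks.csv",
    "destinations": "destinations.csv",
    "open_space_features": "open_space.csv",
    "amenities": "amenities.csv",
    "stops": "stops.csv",
    "stop_times": "stop_times.csv",
    "sa1_covariates": "sa1_covariates.csv",
}


def _table_csv(city: SyntheticCity, name: str) -> str:
    df = getattr(city, name).copy()
    geom_col = _GEOM_TABLES[name]
    if geom_col is not None and geom_col in df.columns:
        df["wkt"] = [
            shapely.to_wkt(g, rounding_precision=-1) for g in df[geom_col]
        ]
        df = df.drop(columns=[geom_col])
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    return buf.getvalue()


def _calendar_csv(city: SyntheticCity) -> str:
    dates = sorted(city.stop_times["service_date"].unique())
    cal = pd.DataFrame(
        {
            "service_date": dates,
            "weekday": [pd.Timestamp(d).weekday() < 5 for d in dates],
        }
    )
    buf = io.StringIO()
    cal.to_csv(buf, index=False)
    return buf.getvalue()


def _metadata_json(city: SyntheticCity) -> str:
    return json.dumps(
        {
            "total_dwellings": city.total_dwellings,
            "district_mb_codes": city.district_mb_codes,
            "zero_dwelling_mb_codes": city.zero_dwelling_mb_codes,
            "disconnected_address_ids": city.disconnected_address_ids,
        },
        indent=1,
        sort_keys=True,
    )


def serialise(city: SyntheticCity) -> dict[str, str]:
    """All fixture files as {file name: text content}."""
    out = {
        _TABLE_FILES[name]: _table_csv(city, name) for name in _TABLE_FILES
    }
    out["calendar.csv"] = _calendar_csv(city)
    out["city.json"] = _metadata_json(city)
    return out


def write_fixtures(city: SyntheticCity, directory) -> list[str]:
    """Write the fixture file set (see :data:`FIXTURE_MANIFEST`); round-trips
    losslessly through :func:`liveability.aggregate_export.read_city`."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    try:
        for fname, content in serialise(city).items():
            (directory / fname).write_text(content)
            written.append(fname)
    except OSError as exc:
        raise OSError(f"failed writing fixtures under {directory}: {exc}") from exc
    return sorted(written)


def city_fingerprint(city: SyntheticCity) -> str:
    """SHA-256 over the serialised fixture set: equal seeds, equal cities."""
    h = hashlib.sha256()
    files = serialise(city)
    for fname in FIXTURE_MANIFEST:
        h.update(fname.encode())
        h.update(files[fname].encode())
    return h.hexdigest()
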