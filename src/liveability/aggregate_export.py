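"""Exclusion rules and tally, dwelling/person-weighted aggregation, and the
published file shapes.

Addresses are flagged for exclusion in priority order (each address counted
once): not urban (mesh block not urban, or zero dwellings), then not in an
SA1 with the area disadvantage index, then invalid network topology (a
walkable catchment below the 16.5 ha plausible minimum, or other
connectivity failures yielding null neighbourhood measures).  Included
addresses are averaged per mesh block (unweighted), and mesh-block
summaries aggregate to seven larger scales (SA1..SA4, suburb, LGA, city)
with dwelling or person weighting.  Threshold indicators also aggregate as
the percentage of dwellings meeting a split criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .pednet import Catchment

AREA_LEVELS = ["meshblock", "sa1", "sa2", "sa3", "sa4", "suburb", "lga", "city"]
LEVEL_COLUMNS = {
    "meshblock": "mb_code", "sa1": "sa1", "sa2": "sa2", "sa3": "sa3",
    "sa4": "sa4", "suburb": "suburb", "lga": "lga", "city": "city",
}


def round_half_up(x: float, ndigits: int = 2) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Exclusions


@dataclass
class ExclusionTally:
    """Summary counts of addresses excluded and included, with percentages
    recomputed from the counts (half-up, two decimals)."""

    total: int
    not_urban: int
    no_index: int
    invalid_small_area: int
    invalid_other: int

    @property
    def not_meeting_inclusion(self) -> int:
        return self.not_urban + self.no_index

    @property
    def invalid_topology(self) -> int:
        return self.invalid_small_area + self.invalid_other

    @property
    def included(self) -> int:
        return self.total - self.not_meeting_inclusion - self.invalid_topology

    def pct(self, count: int) -> float:
        return round_half_up(100.0 * count / self.total, 2)

    def table(self) -> pd.DataFrame:
        rows = [
            ("total address locations", self.total),
            ("does not meet inclusion criteria", self.not_meeting_inclusion),
            ("  not urban", self.not_urban),
            ("  not in an SA1 with disadvantage index", self.no_index),
            ("invalid network topology", self.invalid_topology),
            ("  catchment area below 16.5 ha plausible minimum", self.invalid_small_area),
            ("  other connectivity issues (null results)", self.invalid_other),
            ("included (not excluded)", self.included),
        ]
        return pd.DataFrame(
            [(name, n, self.pct(n)) for name, n in rows],
            columns=["group", "count", "pct"],
        )


def apply_exclusions(
    addresses: pd.DataFrame,
    meshblocks: pd.DataFrame,
    sa1_covariates: pd.DataFrame,
    catchments: dict,
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Flag addresses for exclusion and tally, in priority order
    not_urban -> no_index -> invalid_topology (overlaps counted once).

    ``catchments`` maps address id to :class:`Catchment` (missing entries
    count as null results).  Returns a flags DataFrame indexed like
    ``addresses`` with boolean columns and an ``included`` column.
    """
    mb = meshblocks.set_index("mb_code")
    cov = sa1_covariates.set_index("sa1")

    flags = pd.DataFrame(index=addresses.index)
    mb_of = addresses["mb_code"]
    urban = mb_of.map(mb["urban"]).fillna(False).astype(bool)
    dwellings = mb_of.map(mb["dwellings"]).fillna(0)
    flags["not_urban"] = ~(urban & (dwellings > 0))

    sa1_of = mb_of.map(mb["sa1"])
    has_index = sa1_of.map(cov["has_index"]).fillna(False).astype(bool)
    flags["no_index"] = (~has_index) & ~flags["not_urban"]

    small, other = [], []
    for aid in addresses["address_id"]:
        c = catchments.get(aid)
        if c is None or c.null_result:
            small.append(False)
            other.append(True)
        else:
            small.append(not c.valid)
            other.append(False)
    prior = flags["not_urban"] | flags["no_index"]
    flags["invalid_small_area"] = np.array(small) & ~prior
    flags["invalid_other"] = np.array(other) & ~prior
    flags["included"] = ~(
        flags["not_urban"] | flags["no_index"]
        | flags["invalid_small_area"] | flags["invalid_other"]
    )
    tally = ExclusionTally(
        total=len(addresses),
        not_urban=int(flags["not_urban"].sum()),
        no_index=int(flags["no_index"].sum()),
        invalid_small_area=int(flags["invalid_small_area"].sum()),
        invalid_other=int(flags["invalid_other"].sum()),
    )
    return flags, tally


# ---------------------------------------------------------------------------
# Aggregation


def aggregate_meshblock(
    address_indicators: pd.DataFrame,
    indicator_cols: list[str],
    meshblocks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Unweighted mesh-block means of included addresses.

    Null indicator values are averaged over the non-null members; the count
    of contributing addresses is reported.  Blocks with no included address
    are omitted.  When ``meshblocks`` is given, dwelling/person counts and
    linkage codes are attached.
    """
    df = address_indicators
    if "included" in df.columns:
        df = df[df["included"]]
    g = df.groupby("mb_code")
    out = g[indicator_cols].mean()
    out["n_addresses"] = g.size()
    out = out.reset_index()
    if meshblocks is not None:
        link_cols = [
            c for c in ("dwellings", "persons", "sa1", "sa2", "sa3", "sa4",
                        "suburb", "lga", "city")
            if c in meshblocks.columns
        ]
        out = out.merge(meshblocks[["mb_code"] + link_cols], on="mb_code", how="left")
    return out


def aggregate_area(
    meshblock_summary: pd.DataFrame,
    level: str,
    indicator_cols: list[str],
    weight: str = "dwellings",
) -> pd.DataFrame:
    """Weighted aggregation of mesh-block summaries to a larger scale.

    Per indicator, the weighted mean sum(w_i x_i)/sum(w_i) over blocks with
    non-null values; zero-weight blocks contribute nothing.  Dwelling and
    person counts are summed.  Unresolvable linkage codes raise, naming the
    block.
    """
    if level not in LEVEL_COLUMNS:
        raise ValueError(f"unknown area level {level!r}")
    key = LEVEL_COLUMNS[level]
    if weight not in ("dwellings", "persons"):
        raise ValueError("weight must be 'dwellings' or 'persons'")
    df = meshblock_summary
    bad = df[df[key].isna()]
    if len(bad):
        raise ValueError(
            f"mesh block {bad['mb_code'].iloc[0]!r} has no {level} linkage code"
        )
    rows = []
    for area_id, grp in df.groupby(key, sort=True):
        w = grp[weight].to_numpy(float)
        rec = {"area_id": area_id, "level": level,
               "dwellings": int(grp["dwellings"].sum()),
               "persons": int(grp["persons"].sum()),
               "n_meshblocks": len(grp)}
        for col in indicator_cols:
            x = grp[col].to_numpy(float)
            ok = ~np.isnan(x) & (w > 0)
            rec[col] = float(np.sum(w[ok] * x[ok]) / np.sum(w[ok])) if ok.any() else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def percent_meeting(values, split: float, direction: str = "<=", weights=None) -> float | None:
    """Percentage of addresses (or of dwellings, when weighted) meeting a
    threshold split, e.g. distance <= 1000 m."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        return None
    if direction == "<=":
        ok = x <= split
    elif direction == ">=":
        ok = x >= split
    else:
        raise ValueError("direction must be '<=' or '>='")
    if weights is None:
        return float(100.0 * ok.sum() / x.size)
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        return None
    return float(100.0 * (w * ok).sum() / w.sum())


# ---------------------------------------------------------------------------
# Published file shapes

_SEP = {"csv": ",", "tsv": "\t", "psv": "|"}


def _write(df: pd.DataFrame, path: Path, kind: str = "csv") -> None:
    try:
        df.to_csv(path, index=False, sep=_SEP[kind])
    except OSError as exc:
        raise OSError(f"failed writing {path}: {exc}") from exc


def _dictionary(df: pd.DataFrame, descriptions: dict | None = None) -> pd.DataFrame:
    descriptions = descriptions or {}
    return pd.DataFrame(
        {
            "variable": df.columns,
            "description": [descriptions.get(c, c.replace("_", " ")) for c in df.columns],
            "dtype": [str(t) for t in df.dtypes],
        }
    )


def format_distance_arrays(arrays_by_category: dict) -> pd.DataFrame:
    """Distance arrays as the published pipe-separated shape: in-field lists
    are comma separated, nulls are empty fields."""
    rows = []
    for category in sorted(arrays_by_category):
        for aid in sorted(arrays_by_category[category]):
            arr = arrays_by_category[category][aid]
            rows.append(
                {
                    "address_id": aid,
                    "category": category,
                    "distances": ",".join(str(d) for d in arr.distances),
                    "closest": "" if arr.closest is None else str(arr.closest),
                }
            )
    return pd.DataFrame(rows, columns=["address_id", "category", "distances", "closest"])


def parse_distance_field(field) -> list[int]:
    if field is None or (isinstance(field, float) and np.isnan(field)) or field == "":
        return []
    return [int(tok) for tok in str(field).split(",")]


def format_od_aos(aos_lists: dict) -> pd.DataFrame:
    """Open-space access lists as the published TSV shape: one row per
    address with a JSON array of {aos_id, distance} objects."""
    rows = []
    for aid in sorted(aos_lists):
        entries = [
            {"aos_id": a, "distance_m": d} for a, d in aos_lists[aid].entries
        ]
        rows.append({"address_id": aid, "attributes": json.dumps(entries)})
    return pd.DataFrame(rows, columns=["address_id", "attributes"])


def format_aos_table(aos_list) -> pd.DataFrame:
    """AOS table with WKT geometry columns (overall, public, water) and a
    serialised attribute map."""
    rows = []
    for aos in aos_list:
        rows.append(
            {
                "aos_id": aos.aos_id,
                "public_area_ha": aos.public_area_ha,
                "attributes": json.dumps(
                    {"co_located": aos.co_located,
                     "has_sport_facility": aos.has_sport_facility},
                    sort_keys=True,
                ),
                "wkt_overall": shapely.to_wkt(aos.geometry, rounding_precision=-1),
                "wkt_public": shapely.to_wkt(aos.public_geometry, rounding_precision=-1),
                "wkt_water": shapely.to_wkt(aos.water_geometry, rounding_precision=-1),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["aos_id", "public_area_ha", "attributes",
                 "wkt_overall", "wkt_public", "wkt_water"],
    )


def export(datasets: dict[str, pd.DataFrame], directory, prefix: str = "liveability") -> list[str]:
    """Write each dataset with a machine-readable data dictionary alongside.

    ``datasets`` maps a short name (optionally suffixed ``.tsv``/``.psv`` to
    pick a dialect) to a DataFrame with stable column order.  Returns the
    written file names.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in datasets.items():
        stem, _, ext = name.partition(".")
        kind = ext or "csv"
        fname = f"{prefix}_{stem}.{kind}"
        _write(df, directory / fname, kind)
        dict_name = f"{prefix}_{stem}_data_dictionary.csv"
        _write(_dictionary(df), directory / dict_name)
        written += [fname, dict_name]
    return sorted(written)


def read_table(path, kind: str | None = None) -> pd.DataFrame:
    path = Path(path)
    kind = kind or path.suffix.lstrip(".")
    return pd.read_csv(path, sep=_SEP.get(kind, ","), keep_default_na=True)


# ---------------------------------------------------------------------------
# Fixture readers (round-trip for the synthetic-city writer)


def read_city(directory):
    """Read a fixture directory written by
    :func:`liveability.synthetic_city.write_fixtures` back into a
    :class:`~liveability.synthetic_city.SyntheticCity`."""
    from . import synthetic_city as sc

    directory = Path(directory)

    def load(fname, geom=True):
        df = pd.read_csv(directory / fname)
        if geom and "wkt" in df.columns:
            df["geometry"] = [shapely.from_wkt(w) for w in df["wkt"]]
            df = df.drop(columns=["wkt"])
        return df

    meta = json.loads((directory / "city.json").read_text())
    stop_times = pd.read_csv(
        directory / "stop_times.csv", dtype={"service_date": str, "departure_time": str}
    )
    return sc.SyntheticCity(
        nodes=load("nodes.csv", geom=False),
        edges=load("edges.csv"),
        addresses=load("addresses.csv"),
        meshblocks=load("meshblocks.csv"),
        destinations=load("destinations.csv"),
        open_space_features=load("open_space.csv"),
        amenities=load("amenities.csv"),
        stops=load("stops.csv"),
        stop_times=stop_times,
        sa1_covariates=load("sa1_covariates.csv", geom=False),
        total_dwellings=meta["total_dwellings"],
        district_mb_codes=meta["district_mb_codes"],
        zero_dwelling_mb_codes=meta["zero_dwelling_mb_codes"],
        disconnected_address_ids=meta["disconnected_address_ids"],
    )
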