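"""Per-address liveability sub-indicators and composite walkability.

The destination registry maps each thematic category to its member
destination types and their recommended access distance thresholds (metres):

* social infrastructure (16 members across five categories):
  community/culture/leisure, education, health/social services,
  sport/recreation and early years;
* fresh food and convenience categories;
* regular public transport (400 m) and large public open space (400 m).

A category score is the mean of its member access scores (soft by default);
``daily_living_access_1600m`` sums access to a supermarket (pooled across
sources), any public transport stop, and a convenience store, each at
1600 m (score out of 3); ``social_infrastructure_mix`` sums the 16 social
infrastructure member scores at their own thresholds (score out of 16).
Walkability is the sum of z-scores of dwelling density, street connectivity
and daily living access, standardised within a city or nationally.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import access as access_mod

#: Table of member destination types and thresholds (m) per category.
CATEGORY_MEMBERS: dict[str, dict[str, float]] = {
    "li_community_culture_leisure": {
        "community_centre": 1000,
        "cinema_theatre": 3200,
        "library": 1000,
        "museum_art_gallery": 3200,
    },
    "li_education": {
        "primary_school": 1600,
        "secondary_school": 1600,
    },
    "li_health_services": {
        "aged_care": 1000,
        "pharmacy": 1000,
        "community_health_centre": 1000,
        "dentist": 1000,
        "gp_clinic": 1000,
        "maternal_child_health": 1000,
    },
    "li_sport_rec": {
        "swimming_pool": 1200,
        "sport_rec_facility": 1200,
    },
    "li_early_years": {
        "childcare_quality": 800,
        "childcare_oshc_quality": 1600,
    },
    "li_food": {
        "fruit_veg_grocer": 1000,
        "meat_seafood": 3200,
        "supermarket": 1000,
    },
    "li_convenience": {
        "convenience_store": 1000,
        "newsagent": 3200,
        "petrol_station": 1000,
    },
}

#: The five categories whose members make up the /16 social infrastructure mix.
SOCIAL_INFRA_CATEGORIES = [
    "li_community_culture_leisure",
    "li_education",
    "li_health_services",
    "li_sport_rec",
    "li_early_years",
]

SOCIAL_INFRA_MEMBERS: dict[str, float] = {
    member: threshold
    for cat in SOCIAL_INFRA_CATEGORIES
    for member, threshold in CATEGORY_MEMBERS[cat].items()
}
assert len(SOCIAL_INFRA_MEMBERS) == 16

#: Daily-living members are each evaluated at a 1600 m walking distance.
DAILY_LIVING_THRESHOLD_M = 1600.0

#: Walkability components (z-score sum).
WALKABILITY_COMPONENTS = [
    "li_dwelling_density_1600m",
    "li_street_connectivity_1600m",
    "daily_living_access_1600m",
]


def category_score(
    distances: dict[str, float | None],
    category: str,
    mode: str = "soft",
    k: float = access_mod.DEFAULT_SOFT_K,
) -> float:
    """Mean member access score for one thematic category.

    ``distances`` maps member destination types to closest network distance
    (null = unreachable, scoring 0).  Unknown members raise.
    """
    members = CATEGORY_MEMBERS.get(category)
    if members is None:
        raise KeyError(f"unknown category {category!r}")
    unknown = set(distances) - set(members)
    if unknown:
        raise KeyError(f"unknown members for {category}: {sorted(unknown)}")
    return float(
        np.mean(
            [
                access_mod.score(distances.get(m), t, mode=mode, k=k)
                for m, t in members.items()
            ]
        )
    )


def daily_living(
    supermarket_m: float | None,
    pt_stop_m: float | None,
    convenience_m: float | None,
    mode: str = "soft",
    k: float = access_mod.DEFAULT_SOFT_K,
) -> float:
    """Score out of 3 for access to a supermarket (pooled minimum across
    sources), any public transport stop, and a convenience store within a
    1600 m walking distance."""
    return sum(
        access_mod.score(d, DAILY_LIVING_THRESHOLD_M, mode=mode, k=k)
        for d in (supermarket_m, pt_stop_m, convenience_m)
    )


def social_infrastructure_mix(
    distances: dict[str, float | None],
    mode: str = "soft",
    k: float = access_mod.DEFAULT_SOFT_K,
) -> float:
    """Score out of 16: sum of access scores for the 16 social
    infrastructure member types at their own thresholds.  All 16 members
    must be present (values may be null)."""
    if set(distances) != set(SOCIAL_INFRA_MEMBERS):
        missing = set(SOCIAL_INFRA_MEMBERS) - set(distances)
        extra = set(distances) - set(SOCIAL_INFRA_MEMBERS)
        raise ValueError(
            f"social infrastructure mix needs exactly the 16 members; "
            f"missing={sorted(missing)}, unexpected={sorted(extra)}"
        )
    return sum(
        access_mod.score(distances[m], t, mode=mode, k=k)
        for m, t in SOCIAL_INFRA_MEMBERS.items()
    )


def link_sa1(sa1_code, sa1_covariates: pd.DataFrame) -> dict:
    """Copy SA1-level covariates onto an address record.

    Returns housing stress %, local employment %, the area disadvantage
    index, and ``no_index`` flagging an SA1 that lacks the disadvantage
    index (or is unknown), which marks the address for exclusion.
    """
    tab = sa1_covariates.set_index("sa1") if "sa1" in sa1_covariates.columns else sa1_covariates
    if sa1_code not in tab.index:
        return {
            "li_sa1_30_40_housing_stress": np.nan,
            "li_sa1_sa3_local_employment": np.nan,
            "disadvantage_index": np.nan,
            "no_index": True,
        }
    row = tab.loc[sa1_code]
    has_index = bool(row["has_index"])
    return {
        "li_sa1_30_40_housing_stress": float(row["pct_housing_stress"]),
        "li_sa1_sa3_local_employment": float(row["pct_local_employment"]),
        "disadvantage_index": float(row["disadvantage_index"]) if has_index else np.nan,
        "no_index": not has_index,
    }


def walkability(
    df: pd.DataFrame,
    scope: str = "city",
    city_col: str = "city",
    components=None,
) -> pd.Series:
    """Walkability index: sum of component z-scores (population SD),
    standardised within each city or pooled nationally.

    Components must be non-null; a zero-variance component raises naming it.
    """
    components = list(components if components is not None else WALKABILITY_COMPONENTS)
    X = df[components].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("walkability components contain nulls; apply exclusions first")
    out = np.empty(len(df))
    if scope == "national":
        groups = [np.arange(len(df))]
    elif scope == "city":
        cities = df[city_col].to_numpy()
        groups = [np.flatnonzero(cities == c) for c in pd.unique(cities)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for idx in groups:
        z = np.zeros(len(idx))
        for j, comp in enumerate(components):
            col = X[idx, j]
            sd = col.std()
            if sd == 0:
                raise ValueError(f"walkability component {comp} has zero variance")
            z += (col - col.mean()) / sd
        out[idx] = z
    return pd.Series(out, index=df.index, name=f"walkability_{scope}")
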