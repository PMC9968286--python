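"""Urban Liveability Index: a variance-penalised composite of 13
sub-indicators.

Construction follows the Mazziotta-Pareto Index with positive polarity:
sub-indicators are oriented so larger is better (housing stress is
reverse-scaled to represent housing affordability), conditionally capped to
constrain outliers, normalised to mean 100 / SD 10 within the
standardisation scope (each city separately, or all cities pooled for the
national index), and aggregated per address as

    ULI = M - S^2 / M

where M and S are the mean and population standard deviation of the
address's 13 normalised scores.  An address performing at the scope mean on
every sub-indicator scores the benchmark value of 100; uneven performance
across domains is penalised.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The 13 ULI sub-indicator columns, in published order.
ULI_COLUMNS = [
    "li_community_culture_leisure",
    "li_education",
    "li_health_services",
    "li_sport_rec",
    "li_early_years",
    "li_food",
    "li_convenience",
    "li_pt_regular_400m",
    "li_public_os_large_400m",
    "li_street_connectivity_1600m",
    "li_dwelling_density_1600m",
    "li_sa1_30_40_housing_stress",
    "li_sa1_sa3_local_employment",
]

#: Polarity per sub-indicator: -1 reverses a "larger is worse" measure.
POLARITY = {col: 1.0 for col in ULI_COLUMNS}
POLARITY["li_sa1_30_40_housing_stress"] = -1.0  # reverse-scaled: affordability

#: Capping parameters: values beyond CAP_TRIGGER_SD on a tail trigger a
#: linear rescale of that tail's values beyond CAP_INNER_SD so the extreme
#: lands exactly at CAP_TRIGGER_SD.
CAP_INNER_SD = 2.0
CAP_TRIGGER_SD = 3.0


def cap_outliers(values) -> np.ndarray:
    """Conditional outlier transformation, applied independently per tail.

    Only if some value lies beyond mean +/- 3 SD on a tail are that tail's
    values beyond mean +/- 2 SD linearly mapped so the most extreme value
    terminates exactly at 3 SD; values within 2 SD are untouched and rank
    order is preserved.  Uses the pre-capping mean and SD (single pass); a
    zero-SD column is returned unchanged.
    """
    x = np.asarray(values, dtype=float)
    mu, sd = x.mean(), x.std()
    if sd == 0:
        return x.copy()
    z = (x - mu) / sd
    out = x.copy()  # untouched values stay bit-identical
    zmax = z.max()
    if zmax > CAP_TRIGGER_SD:
        hi = z > CAP_INNER_SD
        out[hi] = mu + sd * (
            CAP_INNER_SD
            + (z[hi] - CAP_INNER_SD)
            * ((CAP_TRIGGER_SD - CAP_INNER_SD) / (zmax - CAP_INNER_SD))
        )
    zmin = z.min()
    if zmin < -CAP_TRIGGER_SD:
        lo = z < -CAP_INNER_SD
        out[lo] = mu + sd * (
            -CAP_INNER_SD
            + (z[lo] + CAP_INNER_SD)
            * ((CAP_TRIGGER_SD - CAP_INNER_SD) / (-zmin - CAP_INNER_SD))
        )
    return out


def normalise(values) -> np.ndarray:
    """Normalise to mean 100 and (population) standard deviation 10:
    x -> 100 + 10 (x - mean) / SD."""
    x = np.asarray(values, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot normalise a zero-variance column")
    return 100.0 + 10.0 * (x - x.mean()) / sd


def mpi(row) -> float:
    """Variance-penalised average of one address's normalised scores:
    M - S (S / M), with M the row mean and S the population SD."""
    x = np.asarray(row, dtype=float)
    m = x.mean()
    if m <= 0:
        raise ValueError("row mean must be positive for the penalised MPI")
    s = x.std()
    return float(m - s * (s / m))


def transform_columns(matrix: np.ndarray, column_names=None) -> np.ndarray:
    """Per-column cap -> normalise pipeline on a polarity-aligned matrix."""
    matrix = np.asarray(matrix, dtype=float)
    out = np.empty_like(matrix)
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        if col.std() == 0:
            name = column_names[j] if column_names is not None else f"column {j}"
            raise ValueError(f"sub-indicator {name} is constant within scope")
        out[:, j] = normalise(cap_outliers(col))
    return out


def compute_uli(
    df: pd.DataFrame,
    scope: str = "city",
    city_col: str = "city",
    columns=None,
    polarity: dict | None = None,
) -> pd.Series:
    """ULI per address: polarity alignment -> per-column outlier capping ->
    mean-100/SD-10 normalisation within scope -> per-row penalised MPI.

    ``scope='city'`` standardises within each city (requires ``city_col``);
    ``scope='national'`` pools all addresses.  Excluded addresses must be
    removed beforehand: nulls raise.
    """
    columns = list(columns if columns is not None else ULI_COLUMNS)
    polarity = dict(POLARITY if polarity is None else polarity)
    X = df[columns].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("sub-indicator matrix contains nulls; apply exclusions first")
    for j, col in enumerate(columns):
        X[:, j] = X[:, j] * polarity.get(col, 1.0)

    result = np.empty(len(df))
    if scope == "national":
        groups = [np.arange(len(df))]
    elif scope == "city":
        cities = df[city_col].to_numpy()
        groups = [np.flatnonzero(cities == c) for c in pd.unique(cities)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    for idx in groups:
        norm = transform_columns(X[idx], columns)
        result[idx] = [mpi(row) for row in norm]
    return pd.Series(result, index=df.index, name=f"uli_{scope}")


def scope_mean_row(
    df: pd.DataFrame,
    columns=None,
    polarity: dict | None = None,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> pd.Series:
    """Raw sub-indicator values of a reference address sitting exactly at
    the standardisation-scope mean, so that its ULI equals the benchmark 100.

    "Scope mean" is the column mean at the normalisation step, i.e. after
    the conditional outlier capping.  Because appending the reference row
    perturbs the pre-capping moments slightly, the value is computed as a
    fixed point: iterate v -> per-column post-capping mean of the matrix
    with v appended (a contraction of order 1/n; converges in a few steps).
    When capping does not trigger this reduces to the plain column means.
    """
    columns = list(columns if columns is not None else ULI_COLUMNS)
    polarity = dict(POLARITY if polarity is None else polarity)
    sign = np.array([polarity.get(c, 1.0) for c in columns])
    X = df[columns].to_numpy(dtype=float) * sign
    v = X.mean(axis=0)
    for _ in range(max_iter):
        combined = np.vstack([X, v])
        new = np.array([cap_outliers(combined[:, j]).mean() for j in range(len(columns))])
        if np.max(np.abs(new - v)) < tol:
            v = new
            break
        v = new
    return pd.Series(v * sign, index=columns)


def decile_ranks(values: pd.Series) -> pd.Series:
    """Decile rank (1..10) of each value within its scope, for map export."""
    r = values.rank(method="average", pct=True)
    return np.ceil(r * 10).clip(1, 10).astype(int)
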