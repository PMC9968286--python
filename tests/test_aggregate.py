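"""Exclusion flags and tally, weighted aggregation, percent-meeting
indicators and the published export shapes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from liveability import aggregate_export as agg
from liveability.aggregate_export import (
    ExclusionTally,
    aggregate_area,
    aggregate_meshblock,
    apply_exclusions,
    percent_meeting,
)
from liveability.pednet import Catchment


# --- exclusions -------------------------------------------------------------


def catchment(valid=True, null=False, area_ha=20.0):
    poly = box(0, 0, 100, area_ha * 100)
    return Catchment("x", poly, area_ha * 10_000, 1000.0, valid=valid, null_result=null)


@pytest.fixture
def exclusion_inputs():
    addresses = pd.DataFrame(
        {
            "address_id": ["a1", "a2", "a3", "a4", "a5"],
            "mb_code": ["m_ok", "m_zero", "m_rural", "m_noidx", "m_ok"],
        }
    )
    meshblocks = pd.DataFrame(
        {
            "mb_code": ["m_ok", "m_zero", "m_rural", "m_noidx"],
            "dwellings": [40, 0, 30, 35],
            "urban": [True, True, False, True],
            "sa1": ["s1", "s1", "s1", "s2"],
        }
    )
    cov = pd.DataFrame(
        {
            "sa1": ["s1", "s2"],
            "has_index": [True, False],
            "pct_housing_stress": [10.0, 10.0],
            "pct_local_employment": [50.0, 50.0],
            "disadvantage_index": [1000.0, np.nan],
        }
    )
    catchments = {
        "a1": catchment(valid=True),
        "a2": catchment(valid=True),
        "a3": catchment(valid=True),
        "a4": catchment(valid=True),
        "a5": catchment(valid=False, area_ha=16.2),
    }
    return addresses, meshblocks, cov, catchments


def test_exclusion_reasons_and_priority(exclusion_inputs):
    flags, tally = apply_exclusions(*exclusion_inputs)
    by_id = flags.set_axis(exclusion_inputs[0]["address_id"])
    assert by_id.loc["a1", "included"]
    assert by_id.loc["a2", "not_urban"]  # zero-dwelling block
    assert by_id.loc["a3", "not_urban"]  # non-urban block
    assert by_id.loc["a4", "no_index"]
    assert by_id.loc["a5", "invalid_small_area"]  # 16.2 ha < 16.5 ha
    assert tally.included == 1


def test_priority_counts_overlapping_address_once(exclusion_inputs):
    addresses, meshblocks, cov, catchments = exclusion_inputs
    # make a2 fail all three rules: zero dwellings, no index, tiny catchment
    meshblocks.loc[meshblocks["mb_code"] == "m_zero", "sa1"] = "s2"
    catchments["a2"] = catchment(valid=False, area_ha=1.0)
    flags, tally = apply_exclusions(addresses, meshblocks, cov, catchments)
    assert tally.not_urban + tally.no_index + tally.invalid_topology + tally.included == tally.total
    by_id = flags.set_axis(addresses["address_id"])
    assert by_id.loc["a2", "not_urban"]
    assert not by_id.loc["a2", "no_index"]
    assert not by_id.loc["a2", "invalid_small_area"]


def test_missing_catchment_counts_as_null_result(exclusion_inputs):
    addresses, meshblocks, cov, catchments = exclusion_inputs
    del catchments["a1"]
    _, tally = apply_exclusions(addresses, meshblocks, cov, catchments)
    assert tally.invalid_other == 1


@given(
    nu=st.integers(0, 10_000),
    ni=st.integers(0, 10_000),
    small=st.integers(0, 10_000),
    other=st.integers(0, 10_000),
    inc=st.integers(1, 10_000_000),
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_tally_conservation_and_percentages(nu, ni, small, other, inc):
    total = nu + ni + small + other + inc
    t = ExclusionTally(total, nu, ni, small, other)
    assert t.included == inc
    assert t.not_meeting_inclusion + t.invalid_topology + t.included == t.total
    tab = t.table()
    # percentages recompute from counts, half-up to 2 dp
    for _, row in tab.iterrows():
        assert row["pct"] == agg.round_half_up(100.0 * row["count"] / total, 2)


# --- aggregation ------------------------------------------------------------


def test_meshblock_mean_unweighted():
    df = pd.DataFrame(
        {
            "mb_code": ["m1", "m1", "m2", "m3", "m3"],
            "included": [True, True, True, True, True],
            "x": [2.0, 4.0, 7.0, 1.0, np.nan],
        }
    )
    out = aggregate_meshblock(df, ["x"]).set_index("mb_code")
    assert out.loc["m1", "x"] == 3.0
    assert out.loc["m2", "x"] == 7.0  # single address
    assert out.loc["m3", "x"] == 1.0  # null skipped, mean of non-null
    assert out.loc["m3", "n_addresses"] == 2


def test_meshblock_only_included_addresses():
    df = pd.DataFrame(
        {"mb_code": ["m1", "m1"], "included": [True, False], "x": [2.0, 100.0]}
    )
    out = aggregate_meshblock(df, ["x"])
    assert out["x"].iloc[0] == 2.0


def mb_summary():
    return pd.DataFrame(
        {
            "mb_code": ["m1", "m2", "m3", "m4"],
            "sa1": ["s1", "s1", "s2", "s2"],
            "city": ["c"] * 4,
            "dwellings": [2, 6, 4, 0],
            "persons": [4, 18, 8, 0],
            "x": [10.0, 20.0, 30.0, 99.0],
        }
    )


def test_weighted_mean_example():
    out = aggregate_area(mb_summary(), "sa1", ["x"]).set_index("area_id")
    assert out.loc["s1", "x"] == pytest.approx(17.5)  # (2*10+6*20)/8
    assert out.loc["s2", "x"] == pytest.approx(30.0)  # zero-weight block ignored
    assert out.loc["s1", "dwellings"] == 8
    assert out.loc["s2", "persons"] == 8


def test_uniform_value_invariant_across_levels():
    df = mb_summary()
    df["x"] = 5.5
    for level in ("sa1", "city"):
        out = aggregate_area(df, level, ["x"])
        assert np.allclose(out["x"], 5.5)


def test_person_vs_dwelling_weighting_differ():
    df = mb_summary()
    d = aggregate_area(df, "sa1", ["x"], weight="dwellings").set_index("area_id")
    p = aggregate_area(df, "sa1", ["x"], weight="persons").set_index("area_id")
    assert d.loc["s1", "x"] != p.loc["s1", "x"]  # persons-per-dwelling varies


def test_aggregation_telescoping_exact():
    df = mb_summary()
    direct = aggregate_area(df, "city", ["x"]).set_index("area_id").loc["c", "x"]
    sa1 = aggregate_area(df, "sa1", ["x"])
    sa1["mb_code"] = sa1["area_id"]
    sa1["city"] = "c"
    via = aggregate_area(sa1, "city", ["x"]).set_index("area_id").loc["c", "x"]
    assert abs(direct - via) < 1e-9


def test_unresolvable_linkage_names_block():
    df = mb_summary()
    df.loc[0, "sa1"] = np.nan
    with pytest.raises(ValueError, match="m1"):
        aggregate_area(df, "sa1", ["x"])
    with pytest.raises(ValueError):
        aggregate_area(mb_summary(), "postcode", ["x"])


# --- percent meeting --------------------------------------------------------


def test_percent_meeting_examples():
    assert percent_meeting([500, 900, 1200], 1000, "<=") == pytest.approx(200 / 3)
    assert percent_meeting([1, 2], 5, "<=") == 100.0
    assert percent_meeting([10, 20], 5, "<=") == 0.0
    assert percent_meeting([], 5, "<=") is None
    assert percent_meeting([1, 99, 5], np.inf, "<=") == 100.0


def test_percent_meeting_dwelling_weighted():
    v = [500, 1500]
    assert percent_meeting(v, 1000, "<=", weights=[3, 1]) == 75.0
    assert percent_meeting(v, 1000, ">=", weights=[3, 1]) == 25.0


# --- export round-trips -----------------------------------------------------


def test_export_writes_dictionaries_and_round_trips(tmp_path):
    df = pd.DataFrame({"a": [1, 2], "b": [0.5, np.nan], "c": ["x", "y"]})
    written = agg.export({"demo": df, "wide.tsv": df}, tmp_path, prefix="t")
    assert "t_demo.csv" in written and "t_demo_data_dictionary.csv" in written
    assert "t_wide.tsv" in written
    back = agg.read_table(tmp_path / "t_demo.csv")
    pd.testing.assert_frame_equal(back, df)
    dictionary = agg.read_table(tmp_path / "t_demo_data_dictionary.csv")
    assert list(dictionary["variable"]) == list(df.columns)


def test_distance_array_psv_round_trip():
    from liveability.access import DistanceArray

    arrays = {
        "food": {
            "a1": DistanceArray("a1", "food", [150, 600], 150),
            "a2": DistanceArray("a2", "food", [], None),
        }
    }
    psv = agg.format_distance_arrays(arrays)
    parsed = [agg.parse_distance_field(f) for f in psv["distances"]]
    assert parsed == [[150, 600], []]
    assert all(lst == sorted(lst) for lst in parsed)
    assert list(psv["closest"]) == ["150", ""]
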