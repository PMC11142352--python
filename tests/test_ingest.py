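"""LAR ingestion: GEOID construction, filters, outcome coding, aggregation."""

import numpy as np
import pandas as pd
import pytest

from denialmap import (
    SyntheticConfig,
    aggregate_tracts,
    apply_eligibility,
    classify_outcome,
    complete_case,
    drop_excluded,
    generate,
    prepare_analysis,
    read_lar,
)
from denialmap.ingest import make_geoid
from conftest import lar_row


@pytest.mark.parametrize(
    "state, county, tract, expected",
    [
        ("13", "139", "9501.00", "13139950100"),
        ("1", "1", "1.00", "01001000100"),
        ("13", "139", "101.05", "13139010105"),
        ("13", "139", "9501", "13139950100"),  # integer tract implies .00
        ("13", "139", "9501.5", "13139950150"),
        ("13", "", "9501.00", None),
        ("13", "139", "", None),
        ("XX", "139", "9501.00", None),
    ],
)
def test_geoid_construction(state, county, tract, expected):
    assert make_geoid(state, county, tract) == expected


def test_geoid_roundtrip_with_synthetic_writer():
    """Generator GEOIDs survive the LAR rendering and re-parse exactly."""
    from denialmap.synthetic import to_lar_frame

    ds = generate(SyntheticConfig(n_msa=2, grid_rows=3, grid_cols=3, loans_per_tract=3, seed=0))
    lar = to_lar_frame(ds.loans)
    rebuilt = [
        make_geoid(s, c, t)
        for s, c, t in zip(lar["state_code"], lar["county_code"], lar["census_tract_number"])
    ]
    assert rebuilt == list(ds.loans["tract_geoid"])


def test_empty_file_gives_empty_records_and_report(tmp_path):
    path = tmp_path / "empty.csv"
    pd.DataFrame([lar_row()]).head(0).to_csv(path, index=False)
    records, counts, report = prepare_analysis(path)
    assert len(records) == 0 and len(counts) == 0
    assert report.rows_in == 0 and report.retained == 0


def test_missing_required_column_is_a_hard_error(tmp_path):
    frame = pd.DataFrame([lar_row()]).drop(columns=["action_taken"])
    path = tmp_path / "bad.csv"
    frame.to_csv(path, index=False)
    with pytest.raises(ValueError, match="action_taken"):
        read_lar(path)


def test_non_numeric_income_retained_as_missing(tmp_path):
    frame = pd.DataFrame([lar_row(income="oops")])
    path = tmp_path / "one.csv"
    frame.to_csv(path, index=False)
    records, report = read_lar(path)
    assert len(records) == 1
    assert pd.isna(records.loc[0, "applicant_income"])


def test_eligibility_rules(tmp_path):
    frame = pd.DataFrame(
        [
            lar_row(purpose=3),  # refinancing -> dropped
            lar_row(purpose=1, occupancy=1, property_type=1),  # kept
            lar_row(occupancy=2),  # non-owner-occupied -> dropped
            lar_row(property_type=3),  # multifamily -> kept
            lar_row(property_type=2),  # manufactured -> dropped
        ]
    )
    path = tmp_path / "elig.csv"
    frame.to_csv(path, index=False)
    records, _ = read_lar(path)
    kept, report = apply_eligibility(records)
    assert len(kept) == 2
    assert report.drops["not_home_purchase"] == 1
    assert report.drops["ineligible_property_type"] == 1
    assert report.drops["not_owner_occupied"] == 1


@pytest.mark.parametrize(
    "action, expected",
    [
        (1, "approved"),  # loan originated
        (2, "approved"),  # approved, not accepted
        (6, "approved"),  # purchased by the institution
        (8, "approved"),  # preapproval approved, not accepted
        (3, "denied"),  # denied by financial institution
        (7, "denied"),  # preapproval denied
        (4, "excluded"),  # withdrawn
        (5, "excluded"),  # closed for incompleteness
        (9, "excluded"),  # unknown code -> excluded with warning
    ],
)
def test_outcome_classification(action, expected):
    frame = pd.DataFrame([lar_row(action=action)])
    frame["action_taken"] = pd.to_numeric(frame["action_taken"]).astype("Int64")
    out = classify_outcome(frame)
    assert out.loc[0, "outcome"] == expected


def test_unknown_action_counted_as_warning(tmp_path):
    frame = pd.DataFrame([lar_row(action=9), lar_row(action=1)])
    path = tmp_path / "u.csv"
    frame.to_csv(path, index=False)
    records, _ = read_lar(path)
    kept, report = drop_excluded(classify_outcome(records))
    assert report.warnings["unknown_action_taken"] == 1
    assert len(kept) == 1


def test_complete_case_rules(tmp_path):
    frame = pd.DataFrame(
        [
            lar_row(),  # fully populated -> kept, lti = 150/60
            lar_row(income=""),  # missing income -> dropped
            lar_row(income="0"),  # zero income: lti undefined -> dropped
            lar_row(sex=3),  # sex not provided -> dropped
            lar_row(tract=""),  # no tract geoid -> dropped
        ]
    )
    path = tmp_path / "cc.csv"
    frame.to_csv(path, index=False)
    records, _ = read_lar(path)
    kept, report = complete_case(records)
    assert len(kept) == 1
    assert kept.loc[0, "lti"] == pytest.approx(150.0 / 60.0)
    assert report.total_dropped == 4


def test_filter_idempotence(lar_fixture_csv):
    records, _ = read_lar(lar_fixture_csv)
    once, _ = apply_eligibility(records)
    twice, rep2 = apply_eligibility(once)
    pd.testing.assert_frame_equal(once, twice)
    assert rep2.total_dropped == 0
    cc_once, _ = complete_case(classify_outcome(once))
    cc_twice, rep4 = complete_case(cc_once)
    pd.testing.assert_frame_equal(cc_once, cc_twice)
    assert rep4.total_dropped == 0


def test_conservation_on_fixture(lar_fixture_csv):
    """approved + denied + excluded + malformed == rows read, exactly."""
    records, read_report = read_lar(lar_fixture_csv)
    malformed = read_report.drops["malformed_action_taken"]
    classified = classify_outcome(records)
    tally = classified["outcome"].value_counts()
    total = int(tally.sum()) + malformed
    assert total == read_report.rows_in == 50
    assert malformed == 3
    assert set(tally.index) == {"approved", "denied", "excluded"}
    # the merged pipeline report balances too: drops + retained == rows in
    _, _, merged = prepare_analysis(lar_fixture_csv)
    assert merged.total_dropped + merged.retained == merged.rows_in == 50


def test_aggregate_counts_example():
    df = pd.DataFrame(
        {
            "tract_geoid": ["T"] * 10,
            "msa_id": ["M"] * 10,
            "denied": [1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
        }
    )
    counts = aggregate_tracts(df)
    assert counts.loc[0, "n_loans"] == 10
    assert counts.loc[0, "n_denied"] == 3
    assert counts.loc[0, "crude_rate"] == pytest.approx(0.3)


def test_aggregate_rejects_excluded_records():
    df = pd.DataFrame(
        {"tract_geoid": ["T"], "msa_id": ["M"], "outcome": ["excluded"]}
    )
    with pytest.raises(ValueError):
        aggregate_tracts(df)


def test_two_msas_partition_by_bruteforce_recount(lar_fixture_frame, tmp_path):
    """Per-MSA tallies are disjoint partitions of the analysis records."""
    frame = lar_fixture_frame.copy()
    frame.loc[frame.index[:25], "msamd"] = "11111"
    frame.loc[frame.index[25:], "msamd"] = "22222"
    path = tmp_path / "two.csv"
    frame.to_csv(path, index=False)
    records, counts, _ = prepare_analysis(path)
    # brute-force recount, one python loop over rows
    manual: dict[tuple, list] = {}
    for _, r in records.iterrows():
        key = (r["tract_geoid"], r["msa_id"])
        manual.setdefault(key, [0, 0])
        manual[key][0] += 1
        manual[key][1] += int(r["denied"])
    assert len(manual) == len(counts)
    for _, row in counts.iterrows():
        n, d = manual[(row["tract_geoid"], row["msa_id"])]
        assert row["n_loans"] == n and row["n_denied"] == d
    assert counts["n_loans"].sum() == len(records)


def test_round_trip_reproduces_generator_loans(tmp_path):
    ds = generate(SyntheticConfig(n_msa=2, grid_rows=3, grid_cols=3, loans_per_tract=20, seed=13))
    paths = ds.write(tmp_path)
    records, counts, report = prepare_analysis(paths["loans"])
    assert report.retained == len(ds.loans)
    assert list(records["tract_geoid"]) == list(ds.loans["tract_geoid"])
    assert (records["denied"].to_numpy() == ds.loans["denied"].to_numpy()).all()
    assert (records["sex_female"].to_numpy() == ds.loans["sex_female"].to_numpy()).all()
    np.testing.assert_allclose(records["lti"], ds.loans["lti"], rtol=1e-12)
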