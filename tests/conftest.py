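import numpy as np
import pandas as pd
import pytest

from denialmap import SyntheticConfig, generate


def lar_row(
    action=1,
    purpose=1,
    property_type=1,
    occupancy=1,
    amount="150",
    income="60",
    sex=1,
    msa="12345",
    state="13",
    county="139",
    tract="9501.00",
):
    return {
        "action_taken": action,
        "loan_purpose": purpose,
        "property_type": property_type,
        "owner_occupancy": occupancy,
        "loan_amount_000s": amount,
        "applicant_income_000s": income,
        "applicant_sex": sex,
        "msamd": msa,
        "state_code": state,
        "county_code": county,
        "census_tract_number": tract,
    }


@pytest.fixture
def lar_fixture_frame():
    """50 hand-built LAR rows exercising every action-taken code plus
    malformed, ineligible and incomplete records."""
    rows = []
    # every action code 1-8, three times each over two tracts (24 rows)
    for rep in range(3):
        for code in range(1, 9):
            rows.append(lar_row(action=code, tract=f"950{rep % 2 + 1}.00", sex=1 + rep % 2))
    # ineligible: refinance, home improvement, manufactured, non-owner (8 rows)
    for purpose in (2, 3):
        rows.append(lar_row(purpose=purpose))
        rows.append(lar_row(purpose=purpose, action=3))
    rows.append(lar_row(property_type=2))
    rows.append(lar_row(property_type=2, action=4))
    rows.append(lar_row(occupancy=2))
    rows.append(lar_row(occupancy=3, action=3))
    # incomplete: missing income, zero income, missing sex codes, no tract (8)
    rows.append(lar_row(income=""))
    rows.append(lar_row(income="NA"))
    rows.append(lar_row(income="0"))
    rows.append(lar_row(income="-5"))
    rows.append(lar_row(sex=3))
    rows.append(lar_row(sex=4))
    rows.append(lar_row(tract=""))
    rows.append(lar_row(msa=""))
    # malformed action codes (3 rows)
    rows.append(lar_row(action=""))
    rows.append(lar_row(action="XX"))
    rows.append(lar_row(action="NA"))
    # unknown action code (1), multifamily eligible (1), clean denials (5)
    rows.append(lar_row(action=9))
    rows.append(lar_row(property_type=3, action=3))
    for _ in range(5):
        rows.append(lar_row(action=3, tract="9502.00", sex=2))
    frame = pd.DataFrame(rows)
    assert len(frame) == 50
    return frame


@pytest.fixture
def lar_fixture_csv(lar_fixture_frame, tmp_path):
    path = tmp_path / "lar_fixture.csv"
    lar_fixture_frame.to_csv(path, index=False)
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """One 3x3 MSA, 40 loans per tract, moderate spatial structure."""
    cfg = SyntheticConfig(
        n_msa=1, grid_rows=3, grid_cols=3, loans_per_tract=40,
        sigma2_u=0.3, sigma2_v=0.1, seed=42,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def fast_fit(small_dataset):
    """A short but real posterior fit shared across metric tests."""
    from denialmap import fit_msa

    ds = small_dataset
    msa = ds.geometry.msas[0]
    draws, estimates = fit_msa(
        ds.loans, ds.adjacency[msa], n_chains=2, n_iter=800, burn_in=300, seed=7
    )
    return ds, draws, estimates
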