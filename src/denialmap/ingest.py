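"""HMDA Loan Application Register ingestion, eligibility filters and outcome coding.

Reads public-release LAR CSV tables (2010-2014 layout by default, column map
configurable), applies the study's eligibility rules — home-purchase loans on
one-to-four-family or multifamily properties used as owner-occupied principal
dwellings — classifies each application as approved / denied / excluded from
its action-taken code, drops incomplete records (complete-case analysis), and
aggregates per-tract application and denial counts.

Action-taken codes (public LAR):
  1 loan originated                      5 file closed for incompleteness
  2 application approved, not accepted   6 loan purchased by the institution
  3 application denied                   7 preapproval request denied
  4 application withdrawn                8 preapproval approved, not accepted
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_COLUMNS",
    "ACTION_APPROVED",
    "ACTION_DENIED",
    "ACTION_EXCLUDED",
    "FilterReport",
    "read_lar",
    "apply_eligibility",
    "classify_outcome",
    "drop_excluded",
    "complete_case",
    "aggregate_tracts",
    "prepare_analysis",
    "make_geoid",
]

# default column map: public 2010-2014 LAR CSV layout
DEFAULT_COLUMNS: dict[str, str] = {
    "action_taken": "action_taken",
    "loan_purpose": "loan_purpose",
    "property_type": "property_type",
    "occupancy": "owner_occupancy",
    "loan_amount": "loan_amount_000s",
    "applicant_income": "applicant_income_000s",
    "applicant_sex": "applicant_sex",
    "msa_id": "msamd",
    "state": "state_code",
    "county": "county_code",
    "tract": "census_tract_number",
}

# approved: originated / approved-not-accepted / preapproval-approved / purchased
ACTION_APPROVED = frozenset({1, 2, 6, 8})
# denied: denied by institution / preapproval denied
ACTION_DENIED = frozenset({3, 7})
# excluded: withdrawn / closed for incompleteness
ACTION_EXCLUDED = frozenset({4, 5})

PURPOSE_HOME_PURCHASE = 1
PROPERTY_ELIGIBLE = frozenset({1, 3})  # one-to-four family, multifamily
OCCUPANCY_OWNER = 1
SEX_FEMALE, SEX_MALE = 2, 1


@dataclass
class FilterReport:
    """Audit trail: rows dropped per rule in application order, rows retained.

    Invariant on every run: sum of drops + retained == rows in.
    """

    rows_in: int = 0
    drops: dict[str, int] = field(default_factory=dict)
    retained: int = 0
    warnings: dict[str, int] = field(default_factory=dict)

    def record(self, rule: str, n_dropped: int) -> None:
        self.drops[rule] = self.drops.get(rule, 0) + int(n_dropped)

    @property
    def total_dropped(self) -> int:
        return sum(self.drops.values())

    def merged_with(self, other: "FilterReport") -> "FilterReport":
        out = FilterReport(rows_in=self.rows_in, retained=other.retained)
        out.drops = dict(self.drops)
        for k, n in other.drops.items():
            out.drops[k] = out.drops.get(k, 0) + n
        out.warnings = dict(self.warnings)
        for k, n in other.warnings.items():
            out.warnings[k] = out.warnings.get(k, 0) + n
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "rows_in": self.rows_in,
                "drops": self.drops,
                "retained": self.retained,
                "warnings": self.warnings,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def make_geoid(state, county, tract) -> str | None:
    """11-character census tract GEOID from state, county and tract fields.

    State is zero-padded to 2 digits, county to 3; the tract number
    ("9501.00", "101.05", "9501") becomes a 6-digit code (4 integer + 2
    decimal digits).  Returns None when any part is missing or malformed.
    """
    parts = []
    for raw, width in ((state, 2), (county, 3)):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            return None
        s = str(raw).strip()
        if s.endswith(".0"):
            s = s[:-2]
        if not s.isdigit() or len(s) > width:
            return None
        parts.append(s.zfill(width))
    if tract is None or (isinstance(tract, float) and np.isnan(tract)):
        return None
    t = str(tract).strip()
    whole, _, frac = t.partition(".")
    frac = (frac + "00")[:2]
    if not whole.isdigit() or not frac.isdigit() or len(whole) > 4:
        return None
    return parts[0] + parts[1] + whole.zfill(4) + frac


def read_lar(
    path: str | Path,
    columns: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Read a LAR-style CSV into typed loan records.

    Returns records with canonical column names plus a derived ``tract_geoid``,
    and a report counting malformed rows (unparseable action-taken code),
    which are quarantined rather than silently dropped.  Missing required
    columns raise a ``ValueError`` naming the column.  Non-numeric income or
    amount is retained as missing and left to the complete-case filter.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    report = FilterReport(rows_in=len(raw))
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise ValueError(f"LAR file {path} is missing required column(s): {missing}")

    df = pd.DataFrame(index=raw.index)
    for canon, src in colmap.items():
        df[canon] = raw[src].replace("", pd.NA)

    for code_col in ("action_taken", "loan_purpose", "property_type", "occupancy", "applicant_sex"):
        df[code_col] = pd.to_numeric(df[code_col], errors="coerce").astype("Int64")
    for num_col in ("loan_amount", "applicant_income"):
        df[num_col] = pd.to_numeric(df[num_col], errors="coerce")

    # malformed: no usable action-taken code — quarantined, counted
    malformed = df["action_taken"].isna()
    report.record("malformed_action_taken", malformed.sum())
    df = df[~malformed].copy()

    df["tract_geoid"] = [
        make_geoid(s, c, t)
        for s, c, t in zip(df["state"], df["county"], df["tract"])
    ]
    df["msa_id"] = df["msa_id"].astype("string")
    report.retained = len(df)
    return df.reset_index(drop=True), report


def apply_eligibility(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Keep home-purchase loans, 1-4 family or multifamily property, owner-occupied.

    Rules apply in a fixed, reported order; each drop is attributed to the
    first rule that rejects the record.
    """
    report = FilterReport(rows_in=len(records))
    df = records
    rules = (
        ("not_home_purchase", lambda d: d["loan_purpose"] == PURPOSE_HOME_PURCHASE),
        ("ineligible_property_type", lambda d: d["property_type"].isin(PROPERTY_ELIGIBLE)),
        ("not_owner_occupied", lambda d: d["occupancy"] == OCCUPANCY_OWNER),
    )
    for rule, predicate in rules:
        keep = predicate(df).fillna(False).astype(bool)
        report.record(rule, (~keep).sum())
        df = df[keep]
    report.retained = len(df)
    return df.reset_index(drop=True), report


def classify_outcome(records: pd.DataFrame) -> pd.DataFrame:
    """Attach the approved / denied / excluded outcome from the action code.

    Unknown codes are classified as excluded and counted as a warning by
    callers; the mapping follows the public LAR action-taken code list in the
    module docstring.
    """
    action = records["action_taken"]
    outcome = np.select(
        [action.isin(ACTION_APPROVED), action.isin(ACTION_DENIED), action.isin(ACTION_EXCLUDED)],
        ["approved", "denied", "excluded"],
        default="excluded",  # unknown codes fall through to excluded
    )
    out = records.copy()
    out["outcome"] = outcome
    out["unknown_action"] = ~action.isin(
        sorted(ACTION_APPROVED | ACTION_DENIED | ACTION_EXCLUDED)
    )
    return out


def drop_excluded(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Remove withdrawn / closed-for-incompleteness (and unknown-code) records."""
    report = FilterReport(rows_in=len(records))
    if "outcome" not in records.columns:
        records = classify_outcome(records)
    report.warnings["unknown_action_taken"] = int(records["unknown_action"].sum())
    keep = records["outcome"] != "excluded"
    report.record("withdrawn_or_incomplete", (~keep).sum())
    df = records[keep].reset_index(drop=True)
    report.retained = len(df)
    return df, report


def complete_case(records: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Complete-case filter: drop records missing any analysis variable.

    Requires tract GEOID, MSA id, applicant sex (male/female codes only),
    positive income and loan amount; computes the loan-to-income ratio for
    survivors.  Zero or negative income is treated as missing since the
    ratio is undefined.
    """
    report = FilterReport(rows_in=len(records))
    df = records
    rules = (
        ("missing_tract_geoid", lambda d: d["tract_geoid"].notna()),
        ("missing_msa_id", lambda d: d["msa_id"].notna()),
        ("sex_not_reported", lambda d: d["applicant_sex"].isin([SEX_MALE, SEX_FEMALE])),
        ("missing_or_nonpositive_income", lambda d: d["applicant_income"] > 0),
        ("missing_or_nonpositive_amount", lambda d: d["loan_amount"] > 0),
    )
    for rule, predicate in rules:
        keep = predicate(df).fillna(False).astype(bool)
        report.record(rule, (~keep).sum())
        df = df[keep]
    df = df.copy()
    df["sex_female"] = (df["applicant_sex"] == SEX_FEMALE).astype(int)
    df["lti"] = df["loan_amount"] / df["applicant_income"]
    report.retained = len(df)
    return df.reset_index(drop=True), report


def aggregate_tracts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-tract application and denial counts (records must be approved/denied only).

    Returns columns tract_geoid, msa_id, n_loans, n_denied, crude_rate.
    Tracts with no eligible loans simply do not appear; they may still be
    nodes of the adjacency graph.
    """
    if "outcome" in records.columns and (records["outcome"] == "excluded").any():
        raise ValueError("aggregate_tracts expects only approved/denied records")
    df = records.copy()
    if "denied" not in df.columns:
        df["denied"] = (df["outcome"] == "denied").astype(int)
    counts = (
        df.groupby(["tract_geoid", "msa_id"], as_index=False, observed=True)
        .agg(n_loans=("denied", "size"), n_denied=("denied", "sum"))
        .sort_values(["msa_id", "tract_geoid"], ignore_index=True)
    )
    counts["crude_rate"] = counts["n_denied"] / counts["n_loans"]
    return counts


def prepare_analysis(
    path: str | Path,
    columns: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, FilterReport]:
    """Full ingestion chain: read, eligibility, outcome, exclusion, complete-case.

    Returns (analysis records with ``denied``/``sex_female``/``lti``,
    per-tract counts, merged filter report).
    """
    df, report = read_lar(path, columns)
    df, r2 = apply_eligibility(df)
    df = classify_outcome(df)
    df, r3 = drop_excluded(df)
    df, r4 = complete_case(df)
    df["denied"] = (df["outcome"] == "denied").astype(int)
    counts = aggregate_tracts(df) if len(df) else pd.DataFrame(
        columns=["tract_geoid", "msa_id", "n_loans", "n_denied", "crude_rate"]
    )
    report = report.merged_with(r2).merged_with(r3).merged_with(r4)
    report.retained = len(df)
    return df, counts, report
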