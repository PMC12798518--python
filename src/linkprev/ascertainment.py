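"""Case ascertainment from linked cohort and administrative-claims records.

Turns raw person-level and encounter-level tables into the (n, k) counts that
feed prevalence estimation: deduplicate across cohorts keeping the most
complete record, derive the self-report (MINI-based) case flag as an OR over
diagnostic modules, and apply the administrative case-definition algorithm
(>=1 inpatient diagnostic code, or >=2 outpatient billing codes on distinct
dates within a 24-month window, over a 5-year pre-enrollment lookback).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountData",
    "LinkageError",
    "MINI_MODULES",
    "WINDOW_DAYS",
    "lookback_days",
    "dedup_link",
    "mini_case_flag",
    "admin_case_flag",
    "admin_case_flags",
    "counts",
]

#: Maximum day span between two qualifying outpatient codes ("24-month period").
WINDOW_DAYS = 730

#: MINI 6.0 modules pooled into the combined mood/anxiety outcome.
MINI_MODULES = (
    "mdd",
    "bipolar",
    "gad",
    "social_phobia",
    "ptsd",
    "ocd",
    "panic",
)


class LinkageError(ValueError):
    """Raised when deterministic linkage keys conflict across records."""


def lookback_days(years: float) -> int:
    """Length of the pre-enrollment lookback in whole days.

    Uses the 365.25-day year so a 5-year lookback spans 1,826 days
    (one embedded leap year).
    """
    if years <= 0:
        raise ValueError("lookback must be positive")
    return int(round(years * 365.25))


@dataclass(frozen=True)
class CountData:
    """Sufficient statistic of one ascertainment source: n persons, k cases."""

    n: int
    k: int
    source_label: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"n must be positive, got {self.n}")
        if not 0 <= self.k <= self.n:
            raise ValueError(f"k must lie in [0, n], got k={self.k}, n={self.n}")

    @property
    def percent(self) -> float:
        """Case percentage k/n * 100."""
        return 100.0 * self.k / self.n

    def to_dict(self) -> dict:
        return {"source": self.source_label, "n": self.n, "k": self.k}


def _check_unique_ids(cohort: pd.DataFrame, label: str) -> None:
    dup = cohort["person_id"].duplicated()
    if dup.any():
        ids = sorted(cohort.loc[dup, "person_id"].unique().tolist())
        raise LinkageError(f"person_id not unique within cohort {label}: {ids[:10]}")


def dedup_link(
    cohort_a: pd.DataFrame, cohort_b: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Merge two cohort tables into one row per person.

    Matching is deterministic on (person_id, date_of_birth). For persons
    enrolled in both cohorts, the record with the higher completeness_score
    is retained; ties go to the earlier enrollment_date, then to cohort A.

    Returns the merged table and the number of excluded duplicate records.

    Raises
    ------
    LinkageError
        If the same person_id carries conflicting dates of birth.
    """
    _check_unique_ids(cohort_a, "A")
    _check_unique_ids(cohort_b, "B")
    merged = pd.concat([cohort_a, cohort_b], ignore_index=True)

    dob_counts = merged.groupby("person_id")["date_of_birth"].nunique()
    conflicts = dob_counts[dob_counts > 1]
    if len(conflicts):
        raise LinkageError(
            "conflicting date_of_birth for person_id(s): "
            f"{sorted(conflicts.index.tolist())}"
        )

    merged = merged.sort_values(
        ["person_id", "completeness_score", "enrollment_date", "cohort_label"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    deduped = merged.drop_duplicates("person_id", keep="first").reset_index(drop=True)
    excluded = len(merged) - len(deduped)
    return deduped, excluded


def mini_case_flag(module_flags: pd.DataFrame, modules=MINI_MODULES) -> pd.Series:
    """Combined mood/anxiety case flag: OR over MINI module indicators.

    ``module_flags`` holds one row per person with 0/1/missing indicators per
    module. The flag is 1 if any module is positive, missing only if every
    module is missing (instrument not administered), else 0.
    """
    unknown = [c for c in module_flags.columns if c not in modules and c != "person_id"]
    if unknown:
        raise KeyError(f"unknown MINI module column(s): {unknown}")
    cols = [c for c in modules if c in module_flags.columns]
    if not cols:
        raise KeyError("no MINI module columns present")
    block = module_flags[cols].astype("Float64")
    any_pos = (block == 1).any(axis=1)
    all_missing = block.isna().all(axis=1)
    flag = pd.Series(
        np.where(any_pos, 1, 0), index=module_flags.index, dtype="Int64"
    )
    flag[all_missing] = pd.NA
    flag.name = "selfreport_case"
    return flag


def admin_case_flag(
    encounters: pd.DataFrame,
    person: str,
    entry_date,
    lookback_years: float = 5.0,
) -> int:
    """Administrative case definition for a single person.

    Returns 1 iff, among mood/anxiety encounters dated within
    [entry_date - lookback, entry_date], there is at least one inpatient
    encounter, or two outpatient encounters on distinct dates no more than
    730 days apart. Codes outside the mood/anxiety groups never qualify.
    """
    rows = encounters[encounters["person_id"] == person]
    return _flag_one(rows, pd.Timestamp(entry_date), lookback_days(lookback_years))


def _flag_one(rows: pd.DataFrame, entry: pd.Timestamp, lb_days: int) -> int:
    if len(rows) == 0:
        return 0
    dates = pd.to_datetime(rows["encounter_date"])
    relevant = rows["dx_group"].isin(["mood", "anxiety"]).to_numpy()
    in_window = (
        (dates >= entry - pd.Timedelta(days=lb_days)) & (dates <= entry)
    ).to_numpy()
    rows = rows[relevant & in_window]
    if len(rows) == 0:
        return 0
    if (rows["setting"] == "inpatient").any():
        return 1
    out_dates = np.unique(
        pd.to_datetime(rows.loc[rows["setting"] == "outpatient", "encounter_date"])
        .to_numpy()
        .astype("datetime64[D]")
    )
    if len(out_dates) < 2:
        return 0
    gaps = np.diff(out_dates).astype("timedelta64[D]").astype(int)
    return int((gaps <= WINDOW_DAYS).any())


def admin_case_flags(
    encounters: pd.DataFrame,
    cohort: pd.DataFrame,
    lookback_years: float = 5.0,
) -> pd.Series:
    """Vectorized administrative case flag for every person in ``cohort``.

    ``cohort`` must carry person_id and enrollment_date (the study entry
    anchoring the lookback). Returns an int Series indexed like ``cohort``.
    """
    lb = lookback_days(lookback_years)
    enc = encounters.copy()
    enc["encounter_date"] = pd.to_datetime(enc["encounter_date"])
    grouped = dict(tuple(enc.groupby("person_id")))
    empty = enc.iloc[0:0]
    out = [
        _flag_one(grouped.get(pid, empty), pd.Timestamp(entry), lb)
        for pid, entry in zip(cohort["person_id"], cohort["enrollment_date"])
    ]
    return pd.Series(out, index=cohort.index, name="admin_case", dtype=int)


def counts(
    flags: pd.Series, source_label: str, drop_missing: bool = True
) -> tuple[CountData, int]:
    """Collapse a person-level case flag into CountData.

    Missing flags (instrument not administered) are dropped and the drop
    count returned alongside, so that n_retained + n_dropped equals the
    linked sample size.
    """
    n_total = len(flags)
    if drop_missing:
        flags = flags.dropna()
    dropped = n_total - len(flags)
    if len(flags) == 0:
        raise ValueError(f"no observations left for source {source_label!r}")
    data = CountData(n=len(flags), k=int((flags == 1).sum()), source_label=source_label)
    return data, dropped
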