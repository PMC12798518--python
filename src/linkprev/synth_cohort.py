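"""Synthetic linked two-cohort data with known ground truth.

Emulates the structure of a prospective opioid-use-disorder cohort linked to
provincial administrative claims: two overlapping cohorts with duplicate
enrollment, a partially administered self-report diagnostic instrument with
known sensitivity/specificity, and an encounter stream engineered so that
the administrative case-definition algorithm recovers a person-level coding
flag drawn with its own sensitivity/specificity. Every downstream stage of
the pipeline is therefore testable against ground truth without any data
access.

The generator draws the person-level administrative flag first and then
materializes encounters consistent with it, so ascertainment run on the
generated claims reproduces the intended flag exactly, for any valid
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .ascertainment import WINDOW_DAYS, lookback_days

__all__ = [
    "DemoMargins",
    "SimConfig",
    "paper_sim_config",
    "generate_population",
    "simulate_self_report",
    "generate_encounters",
    "generate_all",
    "write_cohort_csv",
    "write_encounters_csv",
]


@dataclass(frozen=True)
class DemoMargins:
    """Target demographic margins, conditional on case status (cosmetic:
    drawn independently given true status, no confounding structure)."""

    female_case: float = 0.559
    female_noncase: float = 0.319
    single_case: float = 0.707
    single_noncase: float = 0.660
    unemployed_case: float = 0.698
    unemployed_noncase: float = 0.550
    age_mean_case: float = 37.4
    age_sd_case: float = 10.9
    age_mean_noncase: float = 40.1
    age_sd_noncase: float = 11.4


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; identical config (incl. seed) gives
    bit-identical output tables."""

    true_prevalence: float = 0.59
    n_cohort_a: int = 1333
    n_cohort_b: int = 2369
    duplicate_rate: float = 272 / 1333
    instrument_completion_rate: float = 549 / 1061
    selfreport_sens: float = 0.95
    selfreport_spec: float = 0.84
    admin_sens: float = 0.629
    admin_spec: float = 0.938
    lookback_years: float = 5.0
    enrollment_window: tuple = ("2011-06-01", "2021-04-30")
    censor_rate: float = 83 / 3430
    demo_margins: DemoMargins = field(default_factory=DemoMargins)
    seed: int = 123

    def __post_init__(self) -> None:
        probs = {
            "true_prevalence": self.true_prevalence,
            "duplicate_rate": self.duplicate_rate,
            "instrument_completion_rate": self.instrument_completion_rate,
            "selfreport_sens": self.selfreport_sens,
            "selfreport_spec": self.selfreport_spec,
            "admin_sens": self.admin_sens,
            "admin_spec": self.admin_spec,
            "censor_rate": self.censor_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.n_cohort_a <= 0 or self.n_cohort_b <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.lookback_years <= 0:
            raise ValueError("lookback_years must be positive")
        start, end = pd.Timestamp(self.enrollment_window[0]), pd.Timestamp(
            self.enrollment_window[1]
        )
        if start >= end:
            raise ValueError("enrollment_window start must precede end")

    @property
    def n_duplicates(self) -> int:
        return int(round(self.duplicate_rate * self.n_cohort_a))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "demo_margins" in raw:
            raw["demo_margins"] = DemoMargins(**raw["demo_margins"])
        if "enrollment_window" in raw:
            raw["enrollment_window"] = tuple(raw["enrollment_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["enrollment_window"] = list(self.enrollment_window)
        return d


def paper_sim_config(seed: int = 123) -> SimConfig:
    """The default study conditions: cohort A of 1,333 with 272 dual-enrolled
    (so 3,430 unique persons after linkage with cohort B's 2,369), 549/1,061
    instrument completion among non-duplicated cohort-A persons, true
    prevalence 0.59, self-report sens/spec 0.95/0.84 and administrative
    coding sens/spec 0.629/0.938."""
    return SimConfig(seed=seed)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


def _uniform_dates(rng, start: pd.Timestamp, end: pd.Timestamp, size: int):
    span = (end - start).days
    offsets = rng.integers(0, span + 1, size=size)
    return start + pd.to_timedelta(offsets, unit="D")


def generate_population(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the two cohort tables (A, B) with shared duplicate persons.

    True case status is Bernoulli(true_prevalence) per unique person;
    demographics are drawn to hit the configured margins in expectation.
    Exactly round(duplicate_rate * n_cohort_a) persons appear in both
    cohorts, with differing completeness scores. Instrument completion is
    assigned to cohort-A persons who are not dual-enrolled (the instrument
    was not administered to dual-enrolled participants).
    """
    rng = _rng(config, 0)
    dm = config.demo_margins
    n_dup = config.n_duplicates
    n_unique = config.n_cohort_a + config.n_cohort_b - n_dup

    person_id = np.array([f"P{i:06d}" for i in range(n_unique)])
    true_status = (rng.random(n_unique) < config.true_prevalence).astype(int)
    is_case = true_status == 1

    sex = np.where(
        rng.random(n_unique) < np.where(is_case, dm.female_case, dm.female_noncase),
        "female",
        "male",
    )
    marital = np.where(
        rng.random(n_unique) < np.where(is_case, dm.single_case, dm.single_noncase),
        "single",
        "in_relationship",
    )
    employment = np.where(
        rng.random(n_unique)
        < np.where(is_case, dm.unemployed_case, dm.unemployed_noncase),
        "unemployed",
        "employed",
    )
    age = rng.normal(
        np.where(is_case, dm.age_mean_case, dm.age_mean_noncase),
        np.where(is_case, dm.age_sd_case, dm.age_sd_noncase),
    ).clip(16.0, 85.0)
    censored = (rng.random(n_unique) < config.censor_rate).astype(int)

    start = pd.Timestamp(config.enrollment_window[0])
    end = pd.Timestamp(config.enrollment_window[1])

    # cohort membership: A holds persons 0..n_a-1; a random subset of A is
    # dual-enrolled in B alongside B-only persons n_a..end
    a_idx = np.arange(config.n_cohort_a)
    dup_idx = np.sort(rng.choice(config.n_cohort_a, size=n_dup, replace=False))
    b_only_idx = np.arange(config.n_cohort_a, n_unique)
    b_idx = np.concatenate([dup_idx, b_only_idx])

    enroll_a = _uniform_dates(rng, start, end, len(a_idx))
    enroll_b = _uniform_dates(rng, start, end, len(b_idx))

    # one date of birth per person, anchored at the first enrollment seen
    first_enroll = pd.Series(index=np.arange(n_unique), dtype="datetime64[ns]")
    first_enroll.iloc[a_idx] = enroll_a
    first_enroll.iloc[b_only_idx] = enroll_b[n_dup:]
    dob = first_enroll - pd.to_timedelta((age * 365.25).round().astype(int), unit="D")

    score_a = rng.integers(3, 9, size=len(a_idx))
    score_b = rng.integers(3, 9, size=len(b_idx))
    # duplicate pairs must differ in completeness so the dedup rule is forced
    dup_pos = np.arange(n_dup)  # duplicates sit first in the B index order
    same = score_b[dup_pos] == score_a[dup_idx]
    score_b[dup_pos[same]] = np.where(
        score_a[dup_idx[same]] > 3, score_a[dup_idx[same]] - 1, score_a[dup_idx[same]] + 1
    )

    dup_set = np.zeros(n_unique, dtype=bool)
    dup_set[dup_idx] = True
    completed = np.zeros(len(a_idx), dtype=int)
    eligible = ~dup_set[a_idx]
    completed[eligible] = (
        rng.random(eligible.sum()) < config.instrument_completion_rate
    ).astype(int)

    def build(idx, label, enroll, score, completed_col):
        return pd.DataFrame(
            {
                "person_id": person_id[idx],
                "cohort_label": label,
                "date_of_birth": dob.iloc[idx].to_numpy(),
                "enrollment_date": np.asarray(enroll),
                "age_years": (
                    (np.asarray(enroll) - dob.iloc[idx].to_numpy())
                    / np.timedelta64(1, "D")
                    / 365.25
                ).round(1),
                "sex": sex[idx],
                "marital_status": marital[idx],
                "employment_status": employment[idx],
                "completeness_score": score,
                "instrument_completed": completed_col,
                "selfreport_flag": pd.array([pd.NA] * len(idx), dtype="Int64"),
                "censored": censored[idx],
                "true_status": true_status[idx],
            }
        )

    cohort_a = build(a_idx, "A", enroll_a, score_a, completed)
    cohort_b = build(b_idx, "B", enroll_b, score_b, np.zeros(len(b_idx), dtype=int))
    return cohort_a, cohort_b


def simulate_self_report(cohort: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Fill in the self-report instrument flag for completers.

    Completers with true status 1 flag positive with probability
    selfreport_sens; true-status-0 completers flag positive with probability
    1 - selfreport_spec. Non-completers stay missing.
    """
    if "true_status" not in cohort:
        raise KeyError("cohort must carry true_status")
    rng = _rng(config, 1)
    out = cohort.copy()
    u = rng.random(len(out))
    p_pos = np.where(
        out["true_status"].to_numpy() == 1,
        config.selfreport_sens,
        1.0 - config.selfreport_spec,
    )
    flag = pd.array((u < p_pos).astype(int), dtype="Int64")
    flag[out["instrument_completed"].to_numpy() == 0] = pd.NA
    out["selfreport_flag"] = flag
    return out


def generate_encounters(
    cohort: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate administrative encounters plus the intended per-person flag.

    Each unique person first receives an intended administrative flag drawn
    with admin_sens/admin_spec against true status. Flagged persons get an
    encounter pattern satisfying the case rule inside the lookback (one
    inpatient mood/anxiety code, or two outpatient codes on distinct dates
    <= 730 days apart); unflagged persons get only non-qualifying patterns
    (nothing, a single outpatient code, or two codes > 730 days apart).
    Unrelated ('other') encounters are sprinkled on everyone. Encounters are
    anchored to the enrollment date of the record deduplication retains, so
    the case algorithm reproduces the intended flag exactly.

    ``cohort`` may contain duplicate persons (e.g. the concatenation of both
    cohort tables). Returns (encounters, intended) where ``intended`` has one
    row per unique person: person_id, entry_date, intended_admin.
    """
    lb = lookback_days(config.lookback_years)
    if lb < WINDOW_DAYS + 1:
        raise ValueError(
            f"lookback of {lb} days is shorter than the {WINDOW_DAYS}-day "
            "case-definition window"
        )
    rng = _rng(config, 2)

    retained = cohort.sort_values(
        ["person_id", "completeness_score", "enrollment_date", "cohort_label"],
        ascending=[True, False, True, True],
        kind="mergesort",
    ).drop_duplicates("person_id", keep="first")

    n = len(retained)
    true = retained["true_status"].to_numpy()
    p_flag = np.where(true == 1, config.admin_sens, 1.0 - config.admin_spec)
    intended = (rng.random(n) < p_flag).astype(int)
    entry = pd.to_datetime(retained["enrollment_date"]).to_numpy()

    pattern_u = rng.random(n)
    n_other = rng.poisson(0.5, size=n)

    pids, dates, settings, dx = [], [], [], []

    def add(pid, date, setting, group):
        pids.append(pid)
        dates.append(date)
        settings.append(setting)
        dx.append(group)

    day = np.timedelta64(1, "D")
    for i, (pid, ent) in enumerate(zip(retained["person_id"], entry)):
        if intended[i]:
            group = "mood" if rng.random() < 0.6 else "anxiety"
            if pattern_u[i] < 0.3:
                add(pid, ent - int(rng.integers(0, lb + 1)) * day, "inpatient", group)
            else:
                gap = int(rng.integers(1, WINDOW_DAYS + 1))
                d1 = int(rng.integers(0, lb - gap + 1))
                d2 = d1 + gap
                add(pid, ent - d1 * day, "outpatient", group)
                add(pid, ent - d2 * day, "outpatient", group)
        else:
            if pattern_u[i] < 0.4:
                pass  # no mood/anxiety contact at all
            elif pattern_u[i] < 0.7:
                group = "mood" if rng.random() < 0.6 else "anxiety"
                add(pid, ent - int(rng.integers(0, lb + 1)) * day, "outpatient", group)
            else:
                # two codes too far apart to qualify
                group = "mood" if rng.random() < 0.6 else "anxiety"
                d1 = int(rng.integers(0, lb - WINDOW_DAYS))
                d2 = int(rng.integers(d1 + WINDOW_DAYS + 1, lb + 1))
                add(pid, ent - d1 * day, "outpatient", group)
                add(pid, ent - d2 * day, "outpatient", group)
        for _ in range(n_other[i]):
            setting = "inpatient" if rng.random() < 0.2 else "outpatient"
            add(pid, ent - int(rng.integers(0, lb + 1)) * day, setting, "other")

    encounters = pd.DataFrame(
        {
            "person_id": pids,
            "encounter_date": pd.to_datetime(np.array(dates, dtype="datetime64[D]")),
            "setting": settings,
            "dx_group": dx,
        }
    )
    intended_df = pd.DataFrame(
        {
            "person_id": retained["person_id"].to_numpy(),
            "entry_date": entry,
            "intended_admin": intended,
        }
    )
    return encounters, intended_df


def generate_all(config: SimConfig):
    """One-call pipeline: population, self-report, encounters.

    Returns (cohort_a, cohort_b, encounters, intended).
    """
    cohort_a, cohort_b = generate_population(config)
    cohort_a = simulate_self_report(cohort_a, config)
    combined = pd.concat([cohort_a, cohort_b], ignore_index=True)
    encounters, intended = generate_encounters(combined, config)
    return cohort_a, cohort_b, encounters, intended


_DATE_COLS = ("date_of_birth", "enrollment_date", "encounter_date", "entry_date")


def _write_csv(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in _DATE_COLS:
        if col in out:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, na_rep="")


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Emit a cohort table as CSV: ISO-8601 dates, missing values empty."""
    _write_csv(cohort, path)


def write_encounters_csv(encounters: pd.DataFrame, path) -> None:
    """Emit an encounter table as CSV: ISO-8601 dates."""
    _write_csv(encounters, path)
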