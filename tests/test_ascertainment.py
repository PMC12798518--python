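"""Record linkage, self-report case flag, administrative case algorithm."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from linkprev import (
    admin_case_flag,
    admin_case_flags,
    counts,
    dedup_link,
    mini_case_flag,
)
from linkprev.ascertainment import WINDOW_DAYS, LinkageError, lookback_days


def _cohort(ids, label, completeness=None, enroll=None, dob=None):
    n = len(ids)
    return pd.DataFrame(
        {
            "person_id": ids,
            "cohort_label": label,
            "date_of_birth": pd.to_datetime(dob if dob else ["1980-01-01"] * n),
            "enrollment_date": pd.to_datetime(enroll if enroll else ["2015-01-01"] * n),
            "completeness_score": completeness if completeness is not None else [5] * n,
        }
    )


class TestDedupLink:
    def test_disjoint_cohorts(self):
        merged, excluded = dedup_link(
            _cohort([f"a{i}" for i in range(10)], "A"),
            _cohort([f"b{i}" for i in range(5)], "B"),
        )
        assert len(merged) == 15 and excluded == 0

    def test_study_scale_overlap(self):
        # 1,333 + 2,369 with 272 dual-enrolled -> 3,430 unique persons
        a_ids = [f"p{i}" for i in range(1333)]
        b_ids = a_ids[:272] + [f"q{i}" for i in range(2369 - 272)]
        merged, excluded = dedup_link(_cohort(a_ids, "A"), _cohort(b_ids, "B"))
        assert len(merged) == 3430 and excluded == 272

    def test_most_complete_record_kept(self):
        a = _cohort(["x"], "A", completeness=[4])
        b = _cohort(["x"], "B", completeness=[7])
        merged, _ = dedup_link(a, b)
        assert merged.loc[0, "completeness_score"] == 7
        assert merged.loc[0, "cohort_label"] == "B"

    def test_tie_breaks(self):
        # equal completeness: earlier enrollment wins, then cohort A
        a = _cohort(["x"], "A", completeness=[5], enroll=["2016-01-01"])
        b = _cohort(["x"], "B", completeness=[5], enroll=["2014-01-01"])
        merged, _ = dedup_link(a, b)
        assert merged.loc[0, "cohort_label"] == "B"
        a2 = _cohort(["x"], "A", completeness=[5])
        b2 = _cohort(["x"], "B", completeness=[5])
        merged2, _ = dedup_link(a2, b2)
        assert merged2.loc[0, "cohort_label"] == "A"

    def test_conflicting_dob_raises(self):
        a = _cohort(["x"], "A", dob=["1980-01-01"])
        b = _cohort(["x"], "B", dob=["1981-01-01"])
        with pytest.raises(LinkageError, match="x"):
            dedup_link(a, b)

    def test_idempotent(self):
        a = _cohort(["x", "y"], "A", completeness=[4, 6])
        b = _cohort(["x", "z"], "B", completeness=[7, 5])
        merged, _ = dedup_link(a, b)
        again, excluded = dedup_link(merged[merged.cohort_label == "A"],
                                     merged[merged.cohort_label == "B"])
        assert excluded == 0
        assert sorted(again.person_id) == sorted(merged.person_id)


class TestMiniCaseFlag:
    MODULES = ["mdd", "bipolar", "gad", "social_phobia", "ptsd", "ocd", "panic"]

    def _frame(self, rows):
        return pd.DataFrame(rows, columns=self.MODULES).astype("Float64")

    def test_or_semantics(self):
        flags = mini_case_flag(self._frame([
            [0, 0, 0, 0, 0, 0, 0],          # all negative
            [0, 0, 0, 0, 1, 0, 0],          # PTSD only
            [None] * 7,                      # instrument not administered
            [None, None, 0, None, None, None, None],  # partially missing, no positive
        ]))
        assert flags.tolist() == [0, 1, pd.NA, 0]

    def test_unknown_module_rejected(self):
        bad = self._frame([[0] * 7]).rename(columns={"mdd": "headache"})
        with pytest.raises(KeyError):
            mini_case_flag(bad)

    def test_completer_cohort_counts(self):
        # 311 of 549 completers positive on at least one module
        rng = np.random.default_rng(5)
        rows = np.zeros((549, 7))
        pos = rng.choice(549, size=311, replace=False)
        rows[pos, rng.integers(0, 7, size=311)] = 1
        flags = mini_case_flag(self._frame(rows))
        data, dropped = counts(flags, "self-report")
        assert (data.n, data.k, dropped) == (549, 311, 0)
        assert data.percent == pytest.approx(56.6, abs=0.05)


def _enc(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "encounter_date", "setting", "dx_group"]
    ).assign(encounter_date=lambda d: pd.to_datetime(d.encounter_date))


ENTRY = pd.Timestamp("2016-06-01")


class TestAdminCaseFlag:
    def test_no_encounters(self):
        assert admin_case_flag(_enc([]), "p", ENTRY) == 0

    def test_single_inpatient_qualifies(self):
        enc = _enc([["p", "2013-06-01", "inpatient", "mood"]])  # 3 years back
        assert admin_case_flag(enc, "p", ENTRY) == 1

    def test_two_outpatient_within_window(self):
        enc = _enc([
            ["p", "2014-01-01", "outpatient", "anxiety"],
            ["p", "2015-06-01", "outpatient", "mood"],
        ])
        assert admin_case_flag(enc, "p", ENTRY) == 1

    def test_outpatient_gap_beyond_window_fails(self):
        enc = _enc([
            ["p", "2012-01-01", "outpatient", "anxiety"],
            ["p", "2014-01-15", "outpatient", "anxiety"],  # 745 days later
        ])
        assert admin_case_flag(enc, "p", ENTRY) == 0

    def test_lookback_excludes_old_encounters(self):
        enc = _enc([
            ["p", "2010-06-01", "outpatient", "mood"],   # 6 years before entry
            ["p", "2010-12-01", "outpatient", "mood"],   # 5.5 years before entry
        ])
        assert admin_case_flag(enc, "p", ENTRY) == 0

    def test_same_day_outpatient_claims_do_not_qualify(self):
        enc = _enc([
            ["p", "2015-06-01", "outpatient", "mood"],
            ["p", "2015-06-01", "outpatient", "anxiety"],
        ])
        assert admin_case_flag(enc, "p", ENTRY) == 0

    def test_other_diagnoses_ignored(self):
        enc = _enc([
            ["p", "2015-06-01", "inpatient", "other"],
            ["p", "2015-07-01", "outpatient", "other"],
            ["p", "2015-08-01", "outpatient", "other"],
        ])
        assert admin_case_flag(enc, "p", ENTRY) == 0

    def test_lookback_constant(self):
        assert lookback_days(5) == 1826

    def test_monotone_in_encounters(self):
        enc = _enc([["p", "2015-06-01", "inpatient", "mood"]])
        assert admin_case_flag(enc, "p", ENTRY) == 1
        more = pd.concat([enc, _enc([["p", "2015-07-01", "outpatient", "other"]])])
        assert admin_case_flag(more, "p", ENTRY) == 1


def _brute_force(enc, entry, lb_days):
    """Oracle: enumerate all encounters and pairs explicitly."""
    rows = [
        r for _, r in enc.iterrows()
        if r.dx_group in ("mood", "anxiety")
        and entry - pd.Timedelta(days=lb_days) <= r.encounter_date <= entry
    ]
    if any(r.setting == "inpatient" for r in rows):
        return 1
    out = [r.encounter_date for r in rows if r.setting == "outpatient"]
    for d1, d2 in combinations(out, 2):
        if d1 != d2 and abs((d2 - d1).days) <= WINDOW_DAYS:
            return 1
    return 0


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.data())
def test_admin_flag_matches_brute_force(data):
    n_enc = data.draw(st.integers(0, 8))
    rows = []
    for i in range(n_enc):
        offset = data.draw(st.integers(0, 2600), label=f"offset{i}")
        setting = data.draw(st.sampled_from(["inpatient", "outpatient"]))
        dx = data.draw(st.sampled_from(["mood", "anxiety", "other"]))
        rows.append(["p", ENTRY - pd.Timedelta(days=offset), setting, dx])
    enc = _enc(rows)
    assert admin_case_flag(enc, "p", ENTRY) == _brute_force(enc, ENTRY, 1826)


def test_vectorized_flags_match_scalar():
    rng = np.random.default_rng(11)
    persons = [f"p{i}" for i in range(40)]
    rows = []
    for p in persons:
        for _ in range(rng.integers(0, 5)):
            rows.append([
                p,
                ENTRY - pd.Timedelta(days=int(rng.integers(0, 2500))),
                rng.choice(["inpatient", "outpatient"], p=[0.2, 0.8]),
                rng.choice(["mood", "anxiety", "other"]),
            ])
    enc = _enc(rows)
    cohort = pd.DataFrame({"person_id": persons, "enrollment_date": ENTRY})
    vec = admin_case_flags(enc, cohort)
    scalar = [admin_case_flag(enc, p, ENTRY) for p in persons]
    assert vec.tolist() == scalar


class TestCounts:
    def test_reference_source_counts(self):
        flags = pd.Series([1] * 632 + [0] * 429)
        data, dropped = counts(flags, "cohort A admin")
        assert (data.n, data.k, dropped) == (1061, 632, 0)
        assert data.percent == pytest.approx(59.57, abs=0.005)
        flags_b = pd.Series([1] * 1394 + [0] * 975)
        data_b, _ = counts(flags_b, "cohort B admin")
        assert (data_b.n, data_b.k) == (2369, 1394)
        assert data_b.percent == pytest.approx(58.84, abs=0.005)

    def test_missing_dropped_and_accounted(self):
        flags = pd.Series([1, 0, pd.NA, 1, pd.NA], dtype="Int64")
        data, dropped = counts(flags, "selfreport")
        assert (data.n, data.k, dropped) == (3, 2, 2)
        assert data.n + dropped == 5

    def test_all_zero(self):
        data, _ = counts(pd.Series([0] * 10), "x")
        assert (data.n, data.k) == (10, 0)

    def test_empty_after_drops_raises(self):
        with pytest.raises(ValueError):
            counts(pd.Series([pd.NA, pd.NA], dtype="Int64"), "empty")
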