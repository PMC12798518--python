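"""Ascertain cases from the synthetic linked records.

Reads the CSVs written by 01_simulate_cohort.py, deduplicates the two
cohorts (keeping the most complete record), runs the administrative
case-definition algorithm (>=1 inpatient or >=2 outpatient mood/anxiety
codes within 24 months, 5-year lookback), collapses the flags to (n, k)
counts per source, and reports how faithfully the algorithm recovered the
generator's intended flags. Writes results/counts/*.json.
"""

import json
from pathlib import Path

import pandas as pd

from linkprev import admin_case_flags, counts, dedup_link, elicit_informative

ROOT = Path(__file__).resolve().parents[1] / "results"
SYN = ROOT / "synthetic"
OUT = ROOT / "counts"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dates = ["date_of_birth", "enrollment_date"]
    cohort_a = pd.read_csv(SYN / "cohort_a.csv", parse_dates=dates)
    cohort_b = pd.read_csv(SYN / "cohort_b.csv", parse_dates=dates)
    encounters = pd.read_csv(SYN / "encounters.csv", parse_dates=["encounter_date"])
    intended = pd.read_csv(SYN / "intended_admin.csv")

    merged, excluded = dedup_link(cohort_a, cohort_b)
    print(f"linked persons: {len(merged)} ({excluded} duplicate records excluded)")

    admin = admin_case_flags(encounters, merged, lookback_years=5)
    recovered = pd.Series(
        admin.to_numpy(), index=merged["person_id"].to_numpy()
    )
    target = intended.set_index("person_id")["intended_admin"]
    mismatches = int((recovered != target.loc[recovered.index]).sum())
    print(f"case algorithm vs intended flags: {mismatches} mismatches")

    admin_counts, _ = counts(admin, "admin (merged cohorts)")
    sr_counts, dropped = counts(merged["selfreport_flag"], "self-report completers")
    print(f"administrative: k={admin_counts.k} / n={admin_counts.n} "
          f"({admin_counts.percent:.2f}%)")
    print(f"self-report: k={sr_counts.k} / n={sr_counts.n} "
          f"({sr_counts.percent:.2f}%), {dropped} non-completers dropped")

    prior = elicit_informative(admin_counts)
    print(f"elicited admin prior: Beta({prior.alpha:g}, {prior.beta:g})")

    payload = {
        "admin": admin_counts.to_dict(),
        "selfreport": {**sr_counts.to_dict(), "dropped_missing": dropped},
        "admin_prior": prior.to_dict(),
        "algorithm_mismatches": mismatches,
        "dedup_excluded": excluded,
    }
    (OUT / "counts.json").write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {OUT / 'counts.json'}")


if __name__ == "__main__":
    main()
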