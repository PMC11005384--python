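"""Reference group-level summary statistics for the three-severity TBI cohort.

These are the printed demographic and self-report summaries (group sizes,
means ± SDs, and categorical counts) of the chronic traumatic-brain-injury
cohort whose design this package's defaults emulate: 21 uninjured controls
(noTBI), 52 mild TBI (mTBI) and 17 moderate-to-severe TBI (msTBI) Active Duty
Service Members. They serve two purposes: (1) defaults for the synthetic
metadata generator, and (2) inputs to the summary-statistics entry points of
:mod:`fapothole.group_stats`, which reconstruct the cohort's group-comparison
statistics (F, t, χ², effect sizes) from these summaries alone.
"""

from __future__ import annotations

from .group_stats import ContingencyTable, GroupSummary

GROUPS = ("noTBI", "mTBI", "msTBI")

GROUP_SIZES = {"noTBI": 21, "mTBI": 52, "msTBI": 17}

#: measure -> GroupSummary over the three groups (mean ± SD as printed)
THREE_GROUP_SUMMARIES: dict[str, GroupSummary] = {
    "age_years": GroupSummary.from_rows(
        [("noTBI", 21, 29.62, 7.28), ("mTBI", 52, 35.00, 7.81), ("msTBI", 17, 26.41, 7.88)]
    ),
    "education_years": GroupSummary.from_rows(
        [("noTBI", 21, 14.83, 2.79), ("mTBI", 52, 14.75, 2.23), ("msTBI", 17, 13.00, 1.54)]
    ),
    "nsi_total": GroupSummary.from_rows(
        [("noTBI", 21, 8.52, 12.46), ("mTBI", 52, 33.10, 18.53), ("msTBI", 17, 18.06, 15.98)]
    ),
    "pcl5_total": GroupSummary.from_rows(
        [("noTBI", 21, 9.33, 15.13), ("mTBI", 52, 30.36, 20.91), ("msTBI", 17, 21.24, 19.74)]
    ),
    "hit6_total": GroupSummary.from_rows(
        [("noTBI", 21, 4.81, 4.39), ("mTBI", 52, 35.64, 26.50), ("msTBI", 17, 6.24, 7.41)]
    ),
}

#: measures reported only for the two injured groups
TBI_GROUP_SUMMARIES: dict[str, GroupSummary] = {
    "lifetime_tbis": GroupSummary.from_rows(
        [("mTBI", 52, 3.92, 2.46), ("msTBI", 17, 1.94, 2.19)]
    ),
    "months_since_injury": GroupSummary.from_rows(
        [("mTBI", 52, 48.04, 44.19), ("msTBI", 17, 10.29, 18.30)]
    ),
}

CAUSE_CATEGORIES = (
    "motor_vehicle_accident",
    "military_training_deployment",
    "fall_accident",
    "sports",
    "assault_abuse",
)

#: cause-of-most-recent-injury counts, rows = (mTBI, msTBI)
CAUSE_OF_INJURY_TABLE = ContingencyTable(
    row_labels=("mTBI", "msTBI"),
    col_labels=CAUSE_CATEGORIES,
    counts=((13, 17, 13, 7, 2), (5, 1, 9, 0, 2)),
)
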