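"""Data-cleaning rules applied to a raw cohort table.

Three rules, and only three: Trail-Making B times coded 0 ("trail not
completed") become missing; values beyond +/-4 SD of their variable's raw
mean become missing; normal-appearing white matter is recomputed as
WM - WMH.  SDs are computed once on the raw (pre-trim) distribution, so the
operation is idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (COGNITIVE_TESTS, cortical_columns, fa_columns,
                     md_columns, subcortical_columns)

__all__ = ["CleaningReport", "clean_cohort", "age_split"]


@dataclass
class CleaningReport:
    """Per-variable counts of cells set missing, plus derived-variable and
    exclusion tallies."""

    outliers: dict = field(default_factory=dict)
    zero_coded: dict = field(default_factory=dict)
    nawm_recomputed: int = 0
    negative_nawm: int = 0
    subjects_excluded: int = 0
    moments: dict = field(default_factory=dict)   # col -> (mean, sd) used

    @property
    def total_outliers(self) -> int:
        return sum(self.outliers.values())

    def to_json(self, path=None):
        d = {"outliers": self.outliers, "zero_coded": self.zero_coded,
             "nawm_recomputed": self.nawm_recomputed,
             "negative_nawm": self.negative_nawm,
             "subjects_excluded": self.subjects_excluded}
        if path is None:
            return json.dumps(d, indent=2)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def _trim_columns(cohort: pd.DataFrame):
    cand = (COGNITIVE_TESTS + ["tbv", "gm", "wm", "wmh", "nawm"]
            + fa_columns() + md_columns() + cortical_columns()
            + subcortical_columns())
    return [c for c in cand if c in cohort.columns]


def clean_cohort(raw: pd.DataFrame, sd_limit: float = 4.0, moments=None
                 ) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the cleaning rules; returns the cleaned copy and a report.

    Order of operations: zero-coded Trail-Making values first (they are
    sentinels, not measurements), then the +/-4 SD trim with moments taken
    from the raw distribution in a single pass, then the NAWM recomputation
    (negative WM - WMH flagged and set missing).  ``moments`` (a mapping
    column -> (mean, sd), as stored in ``CleaningReport.moments``) reuses
    trim thresholds from an earlier pass, making the operation idempotent.
    """
    required = ["tmtb_time", "wm", "wmh"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"cohort lacks required columns: {missing}")
    out = raw.copy()
    report = CleaningReport()

    zero = out["tmtb_time"] == 0
    report.zero_coded["tmtb_time"] = int(zero.sum())
    out.loc[zero, "tmtb_time"] = np.nan

    for col in _trim_columns(out):
        x = out[col].astype(float)
        if moments is not None and col in moments:
            mu, sd = moments[col]
        else:
            mu, sd = x.mean(), x.std()
        report.moments[col] = (float(mu), float(sd))
        if not np.isfinite(sd) or sd == 0:
            report.outliers[col] = 0
            continue
        bad = (x - mu).abs() > sd_limit * sd
        report.outliers[col] = int(bad.sum())
        out.loc[bad, col] = np.nan

    nawm = out["wm"] - out["wmh"]
    neg = nawm < 0
    report.negative_nawm = int(neg.sum())
    nawm[neg] = np.nan
    out["nawm"] = nawm
    report.nawm_recomputed = int(nawm.notna().sum())
    return out, report


def age_split(cohort: pd.DataFrame, mri_column: str = "gm"
              ) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Split the cohort into middle-aged and older halves.

    The split is balanced on the cognitive-MRI overlap: subjects with an MRI
    measure (``mri_column``) and at least one cognitive test.  Within that
    eligible set the two groups have sizes differing by at most one, with
    age ties at the boundary assigned to the middle-aged group.  Returns
    (middle, older, boundary_age); the full cohort is partitioned by the
    boundary.
    """
    cogs = [c for c in COGNITIVE_TESTS if c in cohort.columns]
    if mri_column not in cohort.columns or not cogs:
        raise ValueError("cohort lacks the columns needed for the overlap "
                         "definition")
    eligible = cohort[mri_column].notna() & \
        cohort[cogs].notna().any(axis=1)
    ages = cohort.loc[eligible, "age"]
    if ages.isna().any():
        raise ValueError("age missing for subjects in the overlap set")
    if ages.nunique() <= 1:
        raise ValueError("degenerate age distribution: all ages equal")
    n = len(ages)
    order = np.sort(ages.to_numpy())
    k = (n + 1) // 2                       # ties go to the lower group
    boundary = float(order[k - 1])
    middle = cohort[cohort["age"] <= boundary]
    older = cohort[cohort["age"] > boundary]
    return middle, older, boundary
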