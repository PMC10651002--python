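"""Retention in antenatal care across gestational-age windows.

Dated visits are assigned to the four recommended ANC windows by GA at
the visit date (half-open, in whole days): ANC 1 [0, 16) weeks, ANC 2
[16, 28), ANC 3 [28, 36), ANC 4 [36, inf).  Undated pre-enrollment
self-reported visits set the ANC 1 flag only — valid because the
analysis subcohort enrolls before 13 weeks, inside window 1.

Two retention statistics are computed per the study definitions:

* sequential retention after window X (X = 1..3): among women who
  attended window X, the share who attended any later window;
* cumulative retention through window k (k = 1..4): the share of the
  whole subcohort who attended windows 1..k without a gap.

Women who deliver before week 36 never open window 4; they are removed
from the denominators of "after ANC 3" sequential retention and of
"ANC 1 to ANC 4" cumulative retention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coverage import CoverageEstimate, UndefinedEstimateError, agresti_coull
from .dating import DAYS_PER_WEEK, GAAnchor, ga_days_at

#: Half-open window bounds in GA days; None = unbounded above.
WINDOW_BOUNDS_DAYS: list[tuple[int, int | None]] = [
    (0, 112),
    (112, 196),
    (196, 252),
    (252, None),
]

N_WINDOWS = 4
WINDOW4_OPEN_WEEKS = 36.0

ATTENDED_COLS = [f"attended_{k}" for k in range(1, N_WINDOWS + 1)]


class WindowAssignmentError(ValueError):
    """A visit cannot be placed in any ANC window."""


@dataclass(frozen=True)
class RetentionResult:
    label: str
    numerator: int
    denominator: int
    estimate: CoverageEstimate


def window_of_ga_days(ga_days: int) -> int:
    """1-based ANC window index for a visit at ``ga_days``."""
    if ga_days < 0:
        raise WindowAssignmentError(f"negative visit GA ({ga_days} days)")
    for k, (lo, hi) in enumerate(WINDOW_BOUNDS_DAYS, start=1):
        if ga_days >= lo and (hi is None or ga_days < hi):
            return k
    raise WindowAssignmentError(f"unassignable GA {ga_days}")  # pragma: no cover


def assign_windows(
    cohort: pd.DataFrame,
    visits: pd.DataFrame,
    anchors: dict[str, GAAnchor],
) -> pd.DataFrame:
    """Per-woman window-attendance flags.

    ``cohort`` must carry ``delivery_ga_weeks`` (from the exclusion
    screen).  Only ``chart_prospective`` visits are dated and assigned;
    a positive self-report count at enrollment sets the ANC 1 flag.
    A visit implying a negative GA, or one falling after delivery,
    raises :class:`WindowAssignmentError` naming the woman.
    """
    if "delivery_ga_weeks" not in cohort.columns:
        raise ValueError("cohort lacks delivery_ga_weeks; run apply_exclusions first")
    flags = {
        wid: np.zeros(N_WINDOWS, dtype=bool) for wid in cohort["woman_id"]
    }
    delivery = cohort.set_index("woman_id")["delivery_ga_weeks"]
    selfrep = cohort.set_index("woman_id")["self_visits_enroll"].fillna(0)

    pros = visits[
        (visits["source"] == "chart_prospective")
        & visits["woman_id"].isin(delivery.index)
    ]
    for row in pros.itertuples(index=False):
        anchor = anchors.get(row.woman_id)
        if anchor is None:
            raise WindowAssignmentError(f"no GA anchor for woman {row.woman_id!r}")
        ga_days = ga_days_at(anchor, row.visit_date.date())
        if ga_days < 0:
            raise WindowAssignmentError(
                f"visit before conception for woman {row.woman_id!r}"
            )
        d = delivery[row.woman_id]
        if not pd.isna(d) and ga_days / DAYS_PER_WEEK > d:
            raise WindowAssignmentError(
                f"visit after delivery for woman {row.woman_id!r}"
            )
        flags[row.woman_id][window_of_ga_days(ga_days) - 1] = True

    out = pd.DataFrame(
        {
            "woman_id": list(flags),
            **{
                col: [flags[w][k] for w in flags]
                for k, col in enumerate(ATTENDED_COLS)
            },
        }
    )
    out.loc[out["woman_id"].map(selfrep).to_numpy() > 0, "attended_1"] = True
    out["delivery_ga_weeks"] = out["woman_id"].map(delivery).to_numpy(dtype=float)
    return out


def sequential_after(flags: pd.DataFrame, x: int, level: float = 0.95) -> RetentionResult:
    """Sequential retention after window ``x`` (x in {1, 2, 3}).

    Denominator: women who attended window x (for x = 3, additionally
    restricted to deliveries at >=36 weeks, since earlier deliveries
    cannot return).  Numerator: of those, women attending any window
    after x.  There is no window after ANC 4, so x = 4 is refused.
    """
    if x not in (1, 2, 3):
        raise ValueError("sequential retention is defined for x in {1, 2, 3}")
    attended_x = flags[f"attended_{x}"].to_numpy(dtype=bool)
    denom_mask = attended_x.copy()
    if x == 3:
        denom_mask &= flags["delivery_ga_weeks"].to_numpy() >= WINDOW4_OPEN_WEEKS
    later = np.zeros(len(flags), dtype=bool)
    for k in range(x + 1, N_WINDOWS + 1):
        later |= flags[f"attended_{k}"].to_numpy(dtype=bool)
    n = int(denom_mask.sum())
    if n == 0:
        raise UndefinedEstimateError(f"no women in the ANC {x} denominator")
    num = int((denom_mask & later).sum())
    return RetentionResult(
        label=f"after_anc{x}",
        numerator=num,
        denominator=n,
        estimate=agresti_coull(num, n, level),
    )


def sequential_retention(flags: pd.DataFrame, level: float = 0.95) -> list[RetentionResult]:
    return [sequential_after(flags, x, level) for x in (1, 2, 3)]


def cumulative_through(flags: pd.DataFrame, k: int, level: float = 0.95) -> RetentionResult:
    """Cumulative retention through window ``k``: attended windows 1..k."""
    if k not in (1, 2, 3, 4):
        raise ValueError("cumulative retention is defined for k in 1..4")
    denom_mask = np.ones(len(flags), dtype=bool)
    if k == 4:
        denom_mask &= flags["delivery_ga_weeks"].to_numpy() >= WINDOW4_OPEN_WEEKS
    chain = np.ones(len(flags), dtype=bool)
    for j in range(1, k + 1):
        chain &= flags[f"attended_{j}"].to_numpy(dtype=bool)
    n = int(denom_mask.sum())
    if n == 0:
        raise UndefinedEstimateError(f"no women in the cumulative ANC {k} denominator")
    num = int((denom_mask & chain).sum())
    return RetentionResult(
        label=f"through_anc{k}",
        numerator=num,
        denominator=n,
        estimate=agresti_coull(num, n, level),
    )


def cumulative_retention(flags: pd.DataFrame, level: float = 0.95) -> list[RetentionResult]:
    return [cumulative_through(flags, k, level) for k in (1, 2, 3, 4)]


def flow_table(flags: pd.DataFrame) -> pd.DataFrame:
    """Counts of the 16 window-attendance patterns (the alluvial data).

    Patterns are 'TFTF'-style strings over windows 1..4; all 16 rows are
    emitted, counts sum to the cohort size, and the per-window column
    margins equal the attendance counts.
    """
    pats = [
        "".join("T" if row[c] else "F" for c in ATTENDED_COLS)
        for _, row in flags.iterrows()
    ]
    counts = pd.Series(pats).value_counts()
    all_pats = [
        f"{a}{b}{c}{d}"
        for a in "TF" for b in "TF" for c in "TF" for d in "TF"
    ]
    return pd.DataFrame(
        {
            "pattern": all_pats,
            "count": [int(counts.get(p, 0)) for p in all_pats],
        }
    )
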