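"""Cohort data model, CSV I/O, validation, and eligibility screening.

A cohort is a pandas DataFrame with one row per pregnancy; visits are a
second DataFrame with one row per dated ANC contact (or an undated
self-reported pre-enrollment count).  Column schemas are fixed and
documented in ``docs/data_dictionary.md``.

Eligibility follows the study's exclusion cascade, applied in a fixed
order so the tallies are disjoint and well defined:

1. miscarriages (pregnancy loss before 28 weeks),
2. implausible documented GA (enrollment <=0 or >=46 weeks; delivery
   <28 or >=46 weeks) or unresolvable GA,
3. loss to follow-up (retained separately for sensitivity analysis).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dating import (
    DAYS_PER_WEEK,
    DEFAULT_DISCREPANCY_LIMIT_DAYS,
    GAAnchor,
    GAEvidence,
    UnresolvableGAError,
    best_ga_anchor,
    ga_days_at,
)

# --------------------------------------------------------------------------
# schema

#: Mandatory cohort columns (data dictionary order).  Further columns are
#: baseline covariates and are preserved verbatim.
COHORT_CORE_COLUMNS = [
    "woman_id",
    "enrollment_date",
    "us_ga_weeks",
    "us_date",
    "lmp_date",
    "fundal_height_cm",
    "recall_months",
    "self_visits_enroll",
    "delivery_date",
    "outcome",
    "ltfu",
    "ltfu_date",
]

#: Covariate columns emitted by the simulator / expected from field data.
COHORT_COVARIATE_COLUMNS = [
    "age_years",
    "district",
    "literate",
    "wealth_q",
    "ethnicity",
    "primiparous",
    "hist_stillbirth",
    "hist_preterm",
    "walk_minutes",
]

VISIT_COLUMNS = ["woman_id", "visit_date", "source"]

DATE_COLUMNS = ["enrollment_date", "us_date", "lmp_date", "delivery_date", "ltfu_date"]
FLOAT_COLUMNS = ["us_ga_weeks", "fundal_height_cm", "age_years", "walk_minutes"]
INT_COLUMNS = ["recall_months", "self_visits_enroll", "wealth_q"]
BOOL_COLUMNS = ["ltfu", "literate", "primiparous", "hist_stillbirth", "hist_preterm"]

OUTCOMES = ("live_birth", "stillbirth", "miscarriage", "unknown")
VISIT_SOURCES = ("chart_prospective", "chart_retrospective", "self_report")

DATE_FORMAT = "%Y-%m-%d"


class SchemaError(ValueError):
    """Input table violates the documented schema."""


class RowError(ValueError):
    """A specific row cannot be parsed or violates an invariant."""


@dataclass(frozen=True)
class ExclusionTally:
    """Disjoint exclusion counts for one screening pass."""

    n_input: int
    n_miscarriage: int
    n_implausible_ga: int
    n_ltfu: int
    n_analysis: int

    def __post_init__(self) -> None:
        expected = (
            self.n_input - self.n_miscarriage - self.n_implausible_ga - self.n_ltfu
        )
        if self.n_analysis != expected:
            raise ValueError("exclusion tally does not balance")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_miscarriage": self.n_miscarriage,
            "n_implausible_ga": self.n_implausible_ga,
            "n_ltfu": self.n_ltfu,
            "n_analysis": self.n_analysis,
        }


# --------------------------------------------------------------------------
# parsing helpers


def _parse_dates(raw: pd.Series, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format=DATE_FORMAT, errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise RowError(
            f"unparseable date {raw[bad].iloc[0]!r} in column {column!r}, row {row}"
        )
    return parsed


def _parse_bool(raw: pd.Series, column: str) -> pd.Series:
    mapping = {
        "True": True, "False": False, "true": True, "false": False,
        "1": True, "0": False, True: True, False: False,
    }
    out = raw.map(lambda v: mapping.get(v, pd.NA) if pd.notna(v) else pd.NA)
    bad = out.isna() & raw.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise RowError(f"non-boolean value in column {column!r}, row {row}")
    return out.astype("boolean")


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce a raw cohort frame to canonical dtypes."""
    df = df.copy()
    for col in DATE_COLUMNS:
        if col in df.columns:
            df[col] = _parse_dates(df[col], col)
    for col in FLOAT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Float64")
    for col in INT_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Int64")
    for col in BOOL_COLUMNS:
        if col in df.columns:
            df[col] = _parse_bool(df[col], col)
    if "woman_id" in df.columns:
        df["woman_id"] = df["woman_id"].astype(str)
    return df


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce the pregnancy-record invariants; returns the frame."""
    missing = [c for c in COHORT_CORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if df["woman_id"].duplicated().any():
        dup = df.loc[df["woman_id"].duplicated(), "woman_id"].iloc[0]
        raise RowError(f"duplicate woman_id {dup!r}")
    if len(df):
        bad_outcome = ~df["outcome"].isin(OUTCOMES)
        if bad_outcome.any():
            raise RowError(
                f"unknown outcome {df.loc[bad_outcome, 'outcome'].iloc[0]!r}"
            )
        neg = df["self_visits_enroll"].fillna(0) < 0
        if neg.any():
            raise RowError("self_visits_enroll must be non-negative")
        ltfu = df["ltfu"].fillna(False).astype(bool)
        # LTFU <=> censored before delivery: no delivery date, an LTFU date
        bad_ltfu = ltfu & (df["delivery_date"].notna() | df["ltfu_date"].isna())
        if bad_ltfu.any():
            raise RowError(
                f"LTFU record {df.loc[bad_ltfu, 'woman_id'].iloc[0]!r} must have "
                "ltfu_date and no delivery_date"
            )
        bad_completed = ~ltfu & df["delivery_date"].isna()
        if bad_completed.any():
            raise RowError(
                f"completed record {df.loc[bad_completed, 'woman_id'].iloc[0]!r} "
                "must have a delivery_date"
            )
    return df


def validate_visits(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    if len(df):
        bad_source = ~df["source"].isin(VISIT_SOURCES)
        if bad_source.any():
            raise RowError(f"unknown source {df.loc[bad_source, 'source'].iloc[0]!r}")
        chart = df["source"].str.startswith("chart")
        if (chart & df["visit_date"].isna()).any():
            raise RowError("chart-sourced visits must be dated")
    return df


# --------------------------------------------------------------------------
# I/O


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV (ISO-8601 dates, UTF-8, comma)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=True, encoding="utf-8")
    missing = [c for c in COHORT_CORE_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    return validate_cohort(_canonicalize(raw))


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a validated cohort so that :func:`read_cohort` round-trips."""
    validate_cohort(df)
    out = df.copy()
    for col in DATE_COLUMNS:
        if col in out.columns:
            out[col] = out[col].dt.strftime(DATE_FORMAT)
    out.to_csv(path, index=False, encoding="utf-8")


def read_visits(path) -> pd.DataFrame:
    raw = pd.read_csv(path, dtype=str, keep_default_na=True, encoding="utf-8")
    missing = [c for c in VISIT_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    raw["visit_date"] = _parse_dates(raw["visit_date"], "visit_date")
    if "woman_id" in raw.columns:
        raw["woman_id"] = raw["woman_id"].astype(str)
    return validate_visits(raw)


def write_visits(df: pd.DataFrame, path) -> None:
    validate_visits(df)
    out = df.copy()
    out["visit_date"] = out["visit_date"].dt.strftime(DATE_FORMAT)
    out.to_csv(path, index=False, encoding="utf-8")


# --------------------------------------------------------------------------
# GA resolution over a table


def _evidence_from_row(row) -> GAEvidence:
    def _num(v):
        return None if pd.isna(v) else float(v)

    return GAEvidence(
        ultrasound_ga_weeks=_num(row.us_ga_weeks),
        ultrasound_date=None if pd.isna(row.us_date) else row.us_date.date(),
        lmp_date=None if pd.isna(row.lmp_date) else row.lmp_date.date(),
        fundal_height_cm=_num(row.fundal_height_cm),
        maternal_recall_months=(
            None if pd.isna(row.recall_months) else int(row.recall_months)
        ),
    )


def resolve_anchors(
    df: pd.DataFrame,
    discrepancy_limit_days: int = DEFAULT_DISCREPANCY_LIMIT_DAYS,
) -> dict[str, GAAnchor]:
    """Resolve a GA anchor per woman; unresolvable records are omitted."""
    anchors: dict[str, GAAnchor] = {}
    for row in df.itertuples(index=False):
        try:
            anchors[row.woman_id] = best_ga_anchor(
                _evidence_from_row(row),
                as_of_date=row.enrollment_date.date(),
                discrepancy_limit_days=discrepancy_limit_days,
            )
        except (UnresolvableGAError, ValueError):
            continue
    return anchors


def _ga_columns(
    df: pd.DataFrame, anchors: dict[str, GAAnchor]
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Per-row enrollment/delivery GA in weeks (NaN if unresolvable) + method."""
    enroll, delivery, method = [], [], []
    for row in df.itertuples(index=False):
        anchor = anchors.get(row.woman_id)
        if anchor is None:
            enroll.append(np.nan)
            delivery.append(np.nan)
            method.append(None)
            continue
        enroll.append(ga_days_at(anchor, row.enrollment_date.date()) / DAYS_PER_WEEK)
        if pd.isna(row.delivery_date):
            delivery.append(np.nan)
        else:
            delivery.append(
                ga_days_at(anchor, row.delivery_date.date()) / DAYS_PER_WEEK
            )
        method.append(anchor.method)
    idx = df.index
    return (
        pd.Series(enroll, index=idx),
        pd.Series(delivery, index=idx),
        pd.Series(method, index=idx),
    )


# --------------------------------------------------------------------------
# exclusion cascade


def apply_exclusions(
    cohort: pd.DataFrame,
    visits: pd.DataFrame | None = None,
    *,
    discrepancy_limit_days: int = DEFAULT_DISCREPANCY_LIMIT_DAYS,
) -> tuple[pd.DataFrame, ExclusionTally]:
    """Screen a cohort into the analysis population.

    Exclusions applied in order: miscarriage, implausible/unresolvable
    GA, loss to follow-up.  Returns the analysis cohort augmented with
    ``enroll_ga_weeks``, ``delivery_ga_weeks`` and ``ga_method`` columns,
    plus the disjoint tally.  LTFU records stay in the input cohort
    (see :func:`ltfu_records`) for the sensitivity analysis.
    """
    validate_cohort(cohort)
    df = cohort.copy()
    anchors = resolve_anchors(df, discrepancy_limit_days)
    enroll_ga, delivery_ga, method = _ga_columns(df, anchors)
    df["enroll_ga_weeks"] = enroll_ga
    df["delivery_ga_weeks"] = delivery_ga
    df["ga_method"] = method

    n_input = len(df)
    miscarriage = df["outcome"] == "miscarriage"
    remainder = df[~miscarriage]

    enroll_ok = (remainder["enroll_ga_weeks"] > 0) & (
        remainder["enroll_ga_weeks"] < 46
    )
    delivery_ok = remainder["delivery_ga_weeks"].isna() | (
        (remainder["delivery_ga_weeks"] >= 28) & (remainder["delivery_ga_weeks"] < 46)
    )
    # unresolvable GA (NaN enrollment) is routed to the implausible bucket
    implausible = ~(enroll_ok.fillna(False) & delivery_ok)
    remainder2 = remainder[~implausible]

    ltfu = remainder2["ltfu"].fillna(False).astype(bool)
    analysis = remainder2[~ltfu].reset_index(drop=True)

    tally = ExclusionTally(
        n_input=n_input,
        n_miscarriage=int(miscarriage.sum()),
        n_implausible_ga=int(implausible.sum()),
        n_ltfu=int(ltfu.sum()),
        n_analysis=len(analysis),
    )
    return analysis, tally


def ltfu_records(
    cohort: pd.DataFrame,
    *,
    discrepancy_limit_days: int = DEFAULT_DISCREPANCY_LIMIT_DAYS,
) -> pd.DataFrame:
    """LTFU records that survive the miscarriage and GA screens.

    These are the women set aside (not analyzed) by
    :func:`apply_exclusions`, augmented with the same GA columns.
    """
    validate_cohort(cohort)
    df = cohort[cohort["outcome"] != "miscarriage"].copy()
    anchors = resolve_anchors(df, discrepancy_limit_days)
    enroll_ga, delivery_ga, method = _ga_columns(df, anchors)
    df["enroll_ga_weeks"] = enroll_ga
    df["delivery_ga_weeks"] = delivery_ga
    df["ga_method"] = method
    ok = (df["enroll_ga_weeks"] > 0) & (df["enroll_ga_weeks"] < 46)
    df = df[ok.fillna(False)]
    return df[df["ltfu"].fillna(False).astype(bool)].reset_index(drop=True)


def select_subcohort(
    cohort: pd.DataFrame,
    ga_threshold_weeks: float,
    *,
    complement: bool = False,
) -> pd.DataFrame:
    """Records enrolled strictly below ``ga_threshold_weeks``.

    Requires the ``enroll_ga_weeks`` column added by
    :func:`apply_exclusions`; with ``complement=True`` returns the
    records at or above the threshold instead.
    """
    if "enroll_ga_weeks" not in cohort.columns:
        raise SchemaError("cohort lacks enroll_ga_weeks; run apply_exclusions first")
    if cohort["enroll_ga_weeks"].isna().any():
        raise RowError("enrollment GA unresolved for some records")
    mask = cohort["enroll_ga_weeks"] < ga_threshold_weeks
    if complement:
        mask = ~mask
    return cohort[mask].reset_index(drop=True)
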