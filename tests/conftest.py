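"""Shared fixtures: record builders and seeded simulated cohorts."""

from __future__ import annotations

import datetime as dt
import itertools

import pandas as pd
import pytest

from anccov.cohort import (
    COHORT_CORE_COLUMNS,
    COHORT_COVARIATE_COLUMNS,
    _canonicalize,
)
from anccov.simulate import SimulationConfig, simulate_cohort

_ids = itertools.count()

LMP = dt.date(2019, 1, 1)


def make_row(**overrides) -> dict:
    """One pregnancy record with sane defaults (LMP 2019-01-01,
    enrollment at ~8.4 weeks, term live birth at ~39.3 weeks)."""
    row = {
        "woman_id": f"T{next(_ids):05d}",
        "enrollment_date": LMP + dt.timedelta(days=59),
        "us_ga_weeks": None,
        "us_date": None,
        "lmp_date": LMP,
        "fundal_height_cm": None,
        "recall_months": None,
        "self_visits_enroll": 0,
        "delivery_date": LMP + dt.timedelta(days=275),
        "outcome": "live_birth",
        "ltfu": False,
        "ltfu_date": None,
    }
    row.update(overrides)
    return row


def make_cohort(rows: list[dict]) -> pd.DataFrame:
    """Canonical cohort frame from record dicts (missing columns -> NA)."""
    df = pd.DataFrame(rows, columns=COHORT_CORE_COLUMNS + [
        c for c in COHORT_COVARIATE_COLUMNS if any(c in r for r in rows)
    ])
    for col in ("enrollment_date", "us_date", "lmp_date", "delivery_date", "ltfu_date"):
        df[col] = pd.to_datetime(df[col])
    return _canonicalize(df)


def make_visits(rows: list[tuple[str, dt.date | None, str]]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["woman_id", "visit_date", "source"])
    df["visit_date"] = pd.to_datetime(df["visit_date"])
    return df


@pytest.fixture(scope="session")
def demo_sim():
    """Demonstration profile: paper-like margins, errors, and LTFU."""
    config = SimulationConfig(n_women=2303)
    cohort, visits, truth = simulate_cohort(config)
    return config, cohort, visits, truth


def clean_config(n_women: int = 2000, **overrides) -> SimulationConfig:
    """Error-free study conditions: exact self-report, no exclusions or
    LTFU, everyone enrolled in the first trimester, near-certain
    delivery after week 36 — the conditions for truth-exact recovery."""
    kw = dict(
        n_women=n_women,
        miscarriage_rate=0.0,
        implausible_ga_rate=0.0,
        ltfu_rate=0.0,
        selfreport_exact_prob=1.0,
        first_trimester_frac=1.0,
        delivery_ga_mean_weeks=39.5,
        delivery_ga_sd_weeks=1.0,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture(scope="session")
def clean_sim():
    config = clean_config(n_women=2000)
    cohort, visits, truth = simulate_cohort(config, seed=7)
    return config, cohort, visits, truth
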