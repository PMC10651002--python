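"""Synthetic pregnancy-cohort generator.

Emulates the statistical structure the analysis assumes, so every
downstream stage is testable with known ground truth: enrollment spread
across gestation with a small first-trimester fraction, delivery GA
concentrated near term, a per-window visit-attendance process with
progressive dropout, a self-report error process, and loss to
follow-up.  Records that exercise the exclusion cascade (miscarriages,
implausible documented GA) are injected at configurable rates.

Attendance across the four ANC windows follows a two-state first-order
chain: marginal attendance per window is fixed by
``window_attendance_probs`` and the dependence between consecutive
windows by ``dropout_persistence`` (rho), via the joint

    P(A_k & A_{k+1}) = p_k p_{k+1} + rho * sqrt(p_k q_k p_{k+1} q_{k+1})

with rho = 0 recovering independence.  Combinations whose implied
transition probabilities leave [0, 1] are rejected at construction.

All randomness flows through numpy Generators seeded as
``default_rng([seed, i])`` per woman ``i``, so adding women does not
perturb existing ones and identical (config, seed) gives byte-identical
output tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import COHORT_CORE_COLUMNS, COHORT_COVARIATE_COLUMNS, VISIT_COLUMNS
from .dating import DAYS_PER_WEEK, DEFAULT_RECALL_DAYS_PER_MONTH
from .retention import WINDOW_BOUNDS_DAYS

#: Earliest plausible first ANC contact, in GA days (~6 weeks).
FIRST_VISIT_FLOOR_DAYS = 42


class ConfigError(ValueError):
    """Simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for one synthetic cohort.

    Defaults are the demonstration profile tuned by construction to the
    cohort's observed margins: ~7% first-trimester enrollment, delivery
    near term with <28-week losses excluded, per-window attendance
    falling from ~81% to ~29%, ~50% exact self-report agreement, and
    ~6.3% loss to follow-up.
    """

    n_women: int = 2303
    seed: int = 20181201
    first_trimester_frac: float = 0.072
    enroll_early_range_weeks: tuple[float, float] = (6.0, 13.0)
    enroll_late_range_weeks: tuple[float, float] = (13.0, 32.0)
    delivery_ga_mean_weeks: float = 39.0
    delivery_ga_sd_weeks: float = 2.0
    miscarriage_rate: float = 0.027
    implausible_ga_rate: float = 0.014
    window_attendance_probs: tuple[float, float, float, float] = (
        0.807,
        0.587,
        0.493,
        0.290,
    )
    dropout_persistence: float = 0.3
    selfreport_exact_prob: float = 0.5
    selfreport_error_spread: int = 2
    ltfu_rate: float = 0.063
    #: Probability each dating-evidence pattern is available.
    evidence_probs: dict = field(
        default_factory=lambda: {
            "ultrasound_early": 0.15,
            "lmp_confirmed": 0.10,
            "lmp": 0.55,
            "fundal_height": 0.12,
            "maternal_recall": 0.08,
        }
    )
    #: Fraction of women with pre-enrollment visits whose charts are also
    #: abstracted retrospectively (feeds the self-report agreement check).
    retrospective_fraction: float = 0.25
    study_start: dt.date = dt.date(2018, 1, 1)
    lmp_span_days: int = 500

    def __post_init__(self) -> None:
        fractions = (
            self.first_trimester_frac,
            self.miscarriage_rate,
            self.implausible_ga_rate,
            self.selfreport_exact_prob,
            self.ltfu_rate,
            self.dropout_persistence,
            self.retrospective_fraction,
            *self.window_attendance_probs,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ConfigError("all rate/probability parameters must lie in [0, 1]")
        if self.n_women < 0 or self.selfreport_error_spread < 0:
            raise ConfigError("counts must be non-negative")
        if abs(sum(self.evidence_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("evidence_probs must sum to 1")
        # raises ConfigError when marginals/persistence are incompatible
        window_transition_probs(
            self.window_attendance_probs, self.dropout_persistence
        )


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth emitted alongside the observed tables.

    ``window_flags`` and ``visits`` reflect the attendance process after
    delivery truncation but before the self-report-error and LTFU
    observation processes; ``params`` are the closed-form expectations
    implied by the configuration.
    """

    window_flags: pd.DataFrame  # woman_id, attended_1..4, delivery_ga_weeks, ...
    visits: pd.DataFrame  # woman_id, ga_days, window, pre_enrollment
    total_visits: pd.Series  # woman_id -> true total count
    params: dict


# --------------------------------------------------------------------------
# attendance chain


def window_transition_probs(
    probs: tuple[float, ...], persistence: float
) -> list[tuple[float, float]]:
    """[(P(A_{k+1}|A_k), P(A_{k+1}|not A_k)) for consecutive windows]."""
    out = []
    for p_a, p_b in zip(probs[:-1], probs[1:]):
        if p_a in (0.0, 1.0):
            out.append((p_b, p_b))
            continue
        joint = p_a * p_b + persistence * np.sqrt(
            p_a * (1 - p_a) * p_b * (1 - p_b)
        )
        q1 = joint / p_a
        q0 = (p_b - joint) / (1 - p_a)
        if not (0.0 <= q1 <= 1.0 and 0.0 <= q0 <= 1.0):
            raise ConfigError(
                f"marginals ({p_a:g}, {p_b:g}) incompatible with "
                f"persistence {persistence:g}"
            )
        out.append((q1, q0))
    return out


def implied_truth(config: SimulationConfig) -> dict:
    """Closed-form expectations of the attendance chain.

    Ignores delivery truncation: per-window marginals, coverage of at
    least one visit, and cumulative retention through each window.
    """
    p = config.window_attendance_probs
    trans = window_transition_probs(p, config.dropout_persistence)
    cumulative = [p[0]]
    for q1, _ in trans:
        cumulative.append(cumulative[-1] * q1)
    p_none = 1 - p[0]
    for _, q0 in trans:
        p_none *= 1 - q0
    return {
        "window_marginals": list(p),
        "coverage_ge1": 1 - p_none,
        "cumulative_retention": cumulative,
    }


def pattern_probabilities(config: SimulationConfig) -> dict[tuple[bool, ...], float]:
    """Probability of each of the 16 attendance patterns under the chain."""
    p = config.window_attendance_probs
    trans = window_transition_probs(p, config.dropout_persistence)
    out: dict[tuple[bool, ...], float] = {}
    for code in range(16):
        pat = tuple(bool((code >> (3 - k)) & 1) for k in range(4))
        prob = p[0] if pat[0] else 1 - p[0]
        for k in range(1, 4):
            q1, q0 = trans[k - 1]
            cond = q1 if pat[k - 1] else q0
            prob *= cond if pat[k] else 1 - cond
        out[pat] = prob
    return out


def apply_selfreport_error(
    true_count: int, config: SimulationConfig, rng: np.random.Generator
) -> int:
    """Observed self-reported count for a true pre-enrollment count.

    With probability ``selfreport_exact_prob`` the true count is
    returned; otherwise a uniform nonzero error in
    {-spread..-1, 1..spread} is added and the result clipped at 0.
    """
    if true_count < 0:
        raise ValueError("true_count must be non-negative")
    spread = config.selfreport_error_spread
    if rng.random() < config.selfreport_exact_prob or spread == 0:
        return true_count
    e = int(rng.integers(1, spread + 1))
    if rng.random() < 0.5:
        e = -e
    return max(true_count + e, 0)


# --------------------------------------------------------------------------
# per-woman generation


def _draw_delivery_days(
    rng: np.random.Generator, config: SimulationConfig, min_days: int
) -> int:
    mean = config.delivery_ga_mean_weeks * DAYS_PER_WEEK
    sd = config.delivery_ga_sd_weeks * DAYS_PER_WEEK
    lo = max(28 * DAYS_PER_WEEK, min_days)
    for _ in range(10_000):
        d = int(round(rng.normal(mean, sd)))
        if lo <= d < 46 * DAYS_PER_WEEK:
            return d
    raise ConfigError("delivery-GA distribution incompatible with bounds")


def _simulate_woman(i: int, config: SimulationConfig, seed: int) -> dict:
    rng = np.random.default_rng([seed, i])
    lmp = config.study_start + dt.timedelta(days=int(rng.integers(0, config.lmp_span_days)))

    u = rng.random()
    if u < config.miscarriage_rate:
        fate = "miscarriage"
    elif u < config.miscarriage_rate + config.implausible_ga_rate:
        fate = "implausible"
    else:
        fate = "normal"

    methods = list(config.evidence_probs)
    method = methods[
        rng.choice(len(methods), p=np.array(list(config.evidence_probs.values())))
    ]
    if fate == "implausible":
        method = "lmp"  # corruption is injected on LMP-dated records only

    # enrollment GA (days)
    early_lo = int(round(config.enroll_early_range_weeks[0] * DAYS_PER_WEEK))
    early_hi = int(round(config.enroll_early_range_weeks[1] * DAYS_PER_WEEK))
    late_hi = int(round(config.enroll_late_range_weeks[1] * DAYS_PER_WEEK))
    if fate == "miscarriage":
        g_e = int(rng.integers(early_lo, 141))
    elif rng.random() < config.first_trimester_frac:
        g_e = int(rng.integers(early_lo, early_hi))
    else:
        g_e = int(rng.integers(early_hi, late_hi + 1))

    recall_months: Optional[int] = None
    if method == "maternal_recall":
        recall_months = max(1, round(g_e / DEFAULT_RECALL_DAYS_PER_MONTH))
        g_e = round(recall_months * DEFAULT_RECALL_DAYS_PER_MONTH)

    # delivery / loss GA (days) and fate-specific corruption
    implausible_mode = None
    if fate == "miscarriage":
        g_d = int(rng.integers(g_e + 7, 28 * DAYS_PER_WEEK))
    elif fate == "implausible":
        implausible_mode = int(rng.integers(0, 3))
        if implausible_mode == 0:  # enrollment before conception (GA <= 0)
            g_e = -int(rng.integers(1, 30))
            g_d = _draw_delivery_days(rng, config, 196)
        elif implausible_mode == 1:  # enrollment GA >= 46 weeks
            g_e = int(rng.integers(322, 350))
            g_d = g_e + int(rng.integers(7, 21))
        else:  # delivery GA >= 46 weeks
            g_d = int(rng.integers(322, 336))
    else:
        g_d = _draw_delivery_days(rng, config, g_e + 7)

    # attendance chain, then truncation at delivery/loss
    p = config.window_attendance_probs
    trans = window_transition_probs(p, config.dropout_persistence)
    chain = [bool(rng.random() < p[0])]
    for q1, q0 in trans:
        chain.append(bool(rng.random() < (q1 if chain[-1] else q0)))
    attended = [
        chain[k] and g_d > WINDOW_BOUNDS_DAYS[k][0] for k in range(4)
    ]

    visit_days: list[int] = []
    visit_windows: list[int] = []
    for k in range(4):
        if not attended[k]:
            continue
        lo = max(WINDOW_BOUNDS_DAYS[k][0], FIRST_VISIT_FLOOR_DAYS)
        hi = WINDOW_BOUNDS_DAYS[k][1]
        hi = g_d if hi is None else min(hi, g_d)
        if hi <= lo:  # window opens but closes before any plausible day
            attended[k] = False
            continue
        visit_days.append(int(rng.integers(lo, hi)))
        visit_windows.append(k + 1)

    # loss to follow-up: censor before delivery, blank delivery fields
    is_ltfu = fate == "normal" and rng.random() < config.ltfu_rate
    censor_day: Optional[int] = None
    if is_ltfu:
        censor_day = int(rng.integers(g_e + 1, g_d))

    observed_days = [
        d for d in visit_days if censor_day is None or d < censor_day
    ]
    pre_days = [d for d in observed_days if d < g_e]
    post_days = [d for d in observed_days if d >= g_e]
    reported = apply_selfreport_error(len(pre_days), config, rng)
    has_retro = bool(pre_days) and rng.random() < config.retrospective_fraction

    # dating evidence, exactly consistent with the conception clock
    us_ga_weeks = us_date = lmp_date = fundal = None
    if method == "ultrasound_early":
        scan = int(rng.integers(FIRST_VISIT_FLOOR_DAYS, min(112, g_e + 1)))
        us_ga_weeks, us_date = scan / DAYS_PER_WEEK, lmp + dt.timedelta(days=scan)
        if rng.random() < 0.5:
            lmp_date = lmp
    elif method == "lmp_confirmed" and g_d > 120:
        # scan stays >= 16 weeks even after the +/-7-day discrepancy, so
        # the hierarchy cannot mistake it for an early (dating) ultrasound
        scan = int(rng.integers(119, min(200, g_d)))
        delta = int(rng.integers(-7, 8))
        us_ga_weeks = (scan + delta) / DAYS_PER_WEEK
        us_date = lmp + dt.timedelta(days=scan)
        lmp_date = lmp
    elif method in ("lmp", "lmp_confirmed"):
        lmp_date = lmp
    elif method == "fundal_height":
        fundal = g_e / DAYS_PER_WEEK
    # maternal_recall: recall_months already set

    enrollment_date = lmp + dt.timedelta(days=g_e)
    record = {
        "woman_id": f"W{i:05d}",
        "enrollment_date": enrollment_date,
        "us_ga_weeks": us_ga_weeks,
        "us_date": us_date,
        "lmp_date": lmp_date,
        "fundal_height_cm": fundal,
        "recall_months": recall_months,
        "self_visits_enroll": reported,
        "delivery_date": None if is_ltfu else lmp + dt.timedelta(days=g_d),
        "outcome": (
            "unknown"
            if is_ltfu
            else (
                "miscarriage"
                if fate == "miscarriage"
                else ("stillbirth" if rng.random() < 0.02 else "live_birth")
            )
        ),
        "ltfu": is_ltfu,
        "ltfu_date": lmp + dt.timedelta(days=censor_day) if is_ltfu else None,
        # covariates, independent of the visit process
        "age_years": float(np.clip(round(rng.normal(27.1, 6.1), 1), 15.0, 49.0)),
        "district": ["Angolela Tera", "Kewet"][int(rng.random() < 0.553)],
        "literate": bool(rng.random() >= 0.454),
        "wealth_q": int(rng.integers(1, 6)),
        "ethnicity": ["Amhara", "Oromo", "Other"][
            int(rng.choice(3, p=[0.913, 0.059, 0.028]))
        ],
        "primiparous": bool(rng.random() < 0.313),
        "hist_stillbirth": bool(rng.random() < 0.053),
        "hist_preterm": bool(rng.random() < 0.02),
        "walk_minutes": float(round(min(rng.exponential(68.0), 360.0), 1)),
    }

    visit_rows = [
        {
            "woman_id": record["woman_id"],
            "visit_date": lmp + dt.timedelta(days=d),
            "source": "chart_prospective",
        }
        for d in post_days
    ]
    if has_retro:
        visit_rows += [
            {
                "woman_id": record["woman_id"],
                "visit_date": lmp + dt.timedelta(days=d),
                "source": "chart_retrospective",
            }
            for d in pre_days
        ]

    truth_visits = [
        {
            "woman_id": record["woman_id"],
            "ga_days": d,
            "window": w,
            "pre_enrollment": d < g_e,
        }
        for d, w in zip(visit_days, visit_windows)
    ]
    truth_flags = {
        "woman_id": record["woman_id"],
        **{f"attended_{k + 1}": attended[k] for k in range(4)},
        "delivery_ga_weeks": g_d / DAYS_PER_WEEK,
        "enroll_ga_days": g_e,
        "ga_method": method,
        "fate": fate,
        "ltfu": is_ltfu,
        "true_pre_enrollment": len(pre_days),
        "true_total": len(visit_days),
    }
    return {
        "record": record,
        "visits": visit_rows,
        "truth_visits": truth_visits,
        "truth_flags": truth_flags,
    }


def simulate_cohort(
    config: SimulationConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """Generate (cohort table, visits table, truth) for ``config``.

    ``seed`` overrides ``config.seed``.  Output tables use the canonical
    schemas of :mod:`anccov.cohort` and are byte-identical across runs
    for identical (config, seed).
    """
    seed = config.seed if seed is None else seed
    results = [_simulate_woman(i, config, seed) for i in range(config.n_women)]

    cohort_cols = COHORT_CORE_COLUMNS + COHORT_COVARIATE_COLUMNS
    cohort = pd.DataFrame(
        [r["record"] for r in results], columns=cohort_cols
    )
    visits = pd.DataFrame(
        [v for r in results for v in r["visits"]], columns=VISIT_COLUMNS
    )
    # canonical dtypes matching read_cohort/read_visits
    from .cohort import DATE_COLUMNS, _canonicalize  # local import avoids cycle

    for col in DATE_COLUMNS:
        cohort[col] = pd.to_datetime(cohort[col])
    cohort = _canonicalize(cohort)
    visits["visit_date"] = pd.to_datetime(visits["visit_date"])
    visits["woman_id"] = visits["woman_id"].astype(str)

    truth_flags = pd.DataFrame(
        [r["truth_flags"] for r in results],
        columns=[
            "woman_id", "attended_1", "attended_2", "attended_3", "attended_4",
            "delivery_ga_weeks", "enroll_ga_days", "ga_method", "fate", "ltfu",
            "true_pre_enrollment", "true_total",
        ],
    )
    truth_visits = pd.DataFrame(
        [v for r in results for v in r["truth_visits"]],
        columns=["woman_id", "ga_days", "window", "pre_enrollment"],
    )
    truth = SimulationTruth(
        window_flags=truth_flags,
        visits=truth_visits,
        total_visits=truth_flags.set_index("woman_id")["true_total"]
        if len(truth_flags)
        else pd.Series(dtype=int),
        params=implied_truth(config),
    )
    return cohort, visits, truth
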