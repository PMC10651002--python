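"""Gestational-age dating.

Resolves each pregnancy's gestational-age (GA) anchor from the best
available evidence, following the conventional clinical hierarchy:
early ultrasound, LMP confirmed against a later ultrasound, LMP alone,
fundal height, and maternal recall of GA in months.

GA is maintained internally in whole days; weeks are derived views.
An anchor is a (reference date, GA-in-days at that date, method) triple
from which GA at any other date follows by day arithmetic.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

DAYS_PER_WEEK = 7

#: Maximum tolerated disagreement (days) between the LMP-implied GA and a
#: >=16-week ultrasound before the LMP date is distrusted.  The clinical
#: guidelines behind the hierarchy do not fix a number; 10 days is a
#: conventional second-trimester redating cut and is config-overridable.
DEFAULT_DISCREPANCY_LIMIT_DAYS = 10

#: Fundal-height dating rule: GA in weeks per centimetre of fundal height.
DEFAULT_FUNDAL_HEIGHT_WEEKS_PER_CM = 1.0

#: Maternal-recall conversion: mean calendar month length in days.
DEFAULT_RECALL_DAYS_PER_MONTH = 365.25 / 12

#: Ultrasound performed before this GA (days) dates the pregnancy directly.
EARLY_ULTRASOUND_LIMIT_DAYS = 16 * DAYS_PER_WEEK

GA_METHODS = (
    "ultrasound_early",
    "lmp_confirmed",
    "lmp",
    "fundal_height",
    "maternal_recall",
)


class UnresolvableGAError(ValueError):
    """No usable gestational-age evidence for a pregnancy."""


class NegativeGAError(ValueError):
    """A date precedes the anchor's conception-equivalent origin."""


@dataclass(frozen=True)
class GAEvidence:
    """Raw dating evidence for one pregnancy, any subset may be present."""

    ultrasound_ga_weeks: Optional[float] = None
    ultrasound_date: Optional[dt.date] = None
    lmp_date: Optional[dt.date] = None
    fundal_height_cm: Optional[float] = None
    maternal_recall_months: Optional[int] = None

    def __post_init__(self) -> None:
        if self.ultrasound_ga_weeks is not None and self.ultrasound_date is None:
            raise ValueError("ultrasound GA requires an ultrasound date")

    @property
    def has_any(self) -> bool:
        return any(
            v is not None
            for v in (
                self.ultrasound_ga_weeks,
                self.lmp_date,
                self.fundal_height_cm,
                self.maternal_recall_months,
            )
        )


@dataclass(frozen=True)
class GAAnchor:
    """Resolved dating: GA equals ``ga_at_reference_days`` on ``reference_date``."""

    reference_date: dt.date
    ga_at_reference_days: int
    method: str

    def __post_init__(self) -> None:
        if self.method not in GA_METHODS:
            raise ValueError(f"unknown GA method {self.method!r}")
        if self.ga_at_reference_days < 0:
            raise ValueError("anchor GA must be non-negative")


def best_ga_anchor(
    evidence: GAEvidence,
    as_of_date: Optional[dt.date] = None,
    *,
    discrepancy_limit_days: int = DEFAULT_DISCREPANCY_LIMIT_DAYS,
    fundal_height_weeks_per_cm: float = DEFAULT_FUNDAL_HEIGHT_WEEKS_PER_CM,
    recall_days_per_month: float = DEFAULT_RECALL_DAYS_PER_MONTH,
) -> GAAnchor:
    """Resolve the dating anchor by the evidence hierarchy.

    Order of preference:

    1. ultrasound performed at <16 weeks GA (``ultrasound_early``);
    2. LMP when a >=16-week ultrasound exists and the LMP-implied GA at
       the scan date disagrees by at most ``discrepancy_limit_days``
       (``lmp_confirmed``);
    3. LMP alone when no ultrasound exists (``lmp``);
    4. fundal height, 1 cm per week by default (``fundal_height``);
    5. maternal recall in months (``maternal_recall``).

    ``as_of_date`` is the date fundal height / recall were measured
    (in cohort data, enrollment); it is required only for those branches.
    A >=16-week ultrasound whose LMP check fails (or with no LMP) never
    dates the pregnancy itself: the hierarchy falls through to (4)/(5)
    and raises :class:`UnresolvableGAError` if neither is available.
    """
    if not evidence.has_any:
        raise UnresolvableGAError("no gestational-age evidence present")

    us_weeks = evidence.ultrasound_ga_weeks
    if us_weeks is not None:
        us_days = round(us_weeks * DAYS_PER_WEEK)
        if us_days < EARLY_ULTRASOUND_LIMIT_DAYS:
            return GAAnchor(evidence.ultrasound_date, us_days, "ultrasound_early")
        if evidence.lmp_date is not None:
            lmp_days_at_scan = (evidence.ultrasound_date - evidence.lmp_date).days
            if abs(lmp_days_at_scan - us_days) <= discrepancy_limit_days:
                return GAAnchor(evidence.lmp_date, 0, "lmp_confirmed")
        # late ultrasound with missing or discordant LMP: fall through
    elif evidence.lmp_date is not None:
        return GAAnchor(evidence.lmp_date, 0, "lmp")

    if evidence.fundal_height_cm is not None:
        if as_of_date is None:
            raise ValueError("fundal-height dating requires as_of_date")
        days = round(
            evidence.fundal_height_cm * fundal_height_weeks_per_cm * DAYS_PER_WEEK
        )
        return GAAnchor(as_of_date, max(days, 0), "fundal_height")

    if evidence.maternal_recall_months is not None:
        if as_of_date is None:
            raise ValueError("maternal-recall dating requires as_of_date")
        days = round(evidence.maternal_recall_months * recall_days_per_month)
        return GAAnchor(as_of_date, max(days, 0), "maternal_recall")

    raise UnresolvableGAError(
        "no usable evidence after hierarchy (discordant late ultrasound)"
    )


def ga_days_at(anchor: GAAnchor, date: dt.date) -> int:
    """GA in whole days at ``date`` under ``anchor`` (may be negative)."""
    return anchor.ga_at_reference_days + (date - anchor.reference_date).days


def ga_at(anchor: GAAnchor, date: dt.date) -> float:
    """GA in fractional weeks at ``date``; raises if before conception."""
    days = ga_days_at(anchor, date)
    if days < 0:
        raise NegativeGAError(
            f"date {date} precedes conception-equivalent of anchor {anchor}"
        )
    return days / DAYS_PER_WEEK


def plausibility_flags(
    ga_enroll_weeks: Optional[float], ga_delivery_weeks: Optional[float]
) -> tuple[bool, bool]:
    """Plausibility of enrollment and delivery GA.

    Enrollment GA is plausible iff 0 < GA < 46 weeks; delivery GA iff
    28 <= GA < 46 weeks.  An absent delivery GA (loss to follow-up) is
    vacuously plausible.
    """
    enroll_ok = ga_enroll_weeks is not None and 0.0 < ga_enroll_weeks < 46.0
    delivery_ok = ga_delivery_weeks is None or 28.0 <= ga_delivery_weeks < 46.0
    return enroll_ok, delivery_ok
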