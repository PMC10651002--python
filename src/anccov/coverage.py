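"""ANC coverage estimation.

Per-woman visit counts combine the self-reported number of visits at
enrollment with visits prospectively abstracted from facility charts
after enrollment.  Coverage of at least k visits (k = 1, 4, 8) is
reported with Agresti-Coull 95% confidence intervals; the visit-count
distribution is summarized by frequencies and by median and IQR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


class UndefinedEstimateError(ValueError):
    """A proportion over an empty denominator was requested."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (report-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CoverageEstimate:
    """A binomial proportion with its Agresti-Coull interval.

    ``proportion`` is always the raw ``numerator / denominator``; the
    interval is centred on the shrunken Agresti-Coull midpoint and
    clipped to [0, 1].  ``numerator`` may be fractional for scenario
    estimates built from expected counts.
    """

    numerator: float
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float

    def as_row(self) -> dict[str, float]:
        return {
            "numerator": self.numerator,
            "denominator": self.denominator,
            "pct": 100 * self.proportion,
            "ci_low": 100 * self.ci_low,
            "ci_high": 100 * self.ci_high,
        }


def agresti_coull(x: float, n: int, level: float = 0.95) -> CoverageEstimate:
    """Agresti-Coull interval for ``x`` successes in ``n`` trials.

    With z the standard-normal quantile at (1+level)/2, the interval is
    a Wald interval computed after adding z^2/2 pseudo-successes and z^2
    pseudo-trials: n~ = n + z^2, p~ = (x + z^2/2)/n~, half-width
    z*sqrt(p~(1-p~)/n~).  The exact quantile (~1.959964 at 95%) is used,
    not 1.96.
    """
    if n < 1:
        raise UndefinedEstimateError("Agresti-Coull interval needs n >= 1")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, n={n}]")
    z = float(stats.norm.ppf((1 + level) / 2))
    n_t = n + z * z
    p_t = (x + z * z / 2) / n_t
    hw = float(z * np.sqrt(p_t * (1 - p_t) / n_t))
    return CoverageEstimate(
        numerator=x,
        denominator=n,
        proportion=x / n,
        ci_low=max(0.0, p_t - hw),
        ci_high=min(1.0, p_t + hw),
        level=level,
    )


# --------------------------------------------------------------------------
# visit-count assembly


def assemble_visit_counts(cohort: pd.DataFrame, visits: pd.DataFrame) -> pd.DataFrame:
    """Per-woman visit counts: self-report at enrollment + prospective chart.

    Counts one visit per distinct ``chart_prospective`` date on/after
    enrollment (a visit is a day; same-day duplicates collapse).
    ``chart_retrospective`` records are excluded from totals — they feed
    only the self-report agreement assessment.  A prospective visit
    dated before enrollment (a data error) is reassigned to the
    pre-enrollment pool only when the woman's self-report count is zero,
    otherwise dropped with a warning, to avoid double counting under
    the self-report + prospective combination rule.

    Returns columns ``woman_id, n_pre_enrollment_selfreport,
    n_prospective, n_total``.
    """
    enroll = cohort.set_index("woman_id")["enrollment_date"]
    selfrep = (
        cohort.set_index("woman_id")["self_visits_enroll"].fillna(0).astype(int)
    )
    pros = visits[visits["source"] == "chart_prospective"]
    pros = pros[pros["woman_id"].isin(enroll.index)]
    pros = pros.drop_duplicates(subset=["woman_id", "visit_date"])

    early = pros["visit_date"] < pros["woman_id"].map(enroll)
    n_extra_pre = pd.Series(0, index=enroll.index, dtype=int)
    if early.any():
        early_counts = pros[early].groupby("woman_id").size()
        for wid, k in early_counts.items():
            if selfrep.get(wid, 0) == 0:
                warnings.warn(
                    f"{k} prospective visit(s) before enrollment for {wid!r}; "
                    "reassigned to the pre-enrollment self-report pool",
                    stacklevel=2,
                )
                n_extra_pre[wid] = int(k)
            else:
                warnings.warn(
                    f"{k} prospective visit(s) before enrollment for {wid!r} "
                    "dropped (self-report already covers pre-enrollment)",
                    stacklevel=2,
                )
    n_pros = pros[~early].groupby("woman_id").size()

    out = pd.DataFrame(
        {
            "woman_id": enroll.index,
            "n_pre_enrollment_selfreport": (selfrep + n_extra_pre).to_numpy(),
            "n_prospective": n_pros.reindex(enroll.index).fillna(0).astype(int).to_numpy(),
        }
    )
    out["n_total"] = out["n_pre_enrollment_selfreport"] + out["n_prospective"]
    return out.reset_index(drop=True)


# --------------------------------------------------------------------------
# indicators and summaries


def coverage_indicators(
    counts: pd.DataFrame,
    thresholds: tuple[int, ...] = (1, 4, 8),
    level: float = 0.95,
) -> dict[str, CoverageEstimate]:
    """Coverage of >=k visits for each threshold, plus the zero-visit share."""
    if len(counts) == 0:
        raise UndefinedEstimateError("empty cohort")
    if list(thresholds) != sorted(thresholds) or min(thresholds) < 1:
        raise ValueError("thresholds must be positive and sorted")
    n = len(counts)
    total = counts["n_total"].to_numpy()
    out = {
        f"ge_{k}": agresti_coull(int((total >= k).sum()), n, level)
        for k in thresholds
    }
    out["zero"] = agresti_coull(int((total == 0).sum()), n, level)
    return out


def visit_distribution(counts: pd.DataFrame) -> pd.DataFrame:
    """Frequency table of total visit counts (k, frequency, percent)."""
    freq = counts["n_total"].value_counts().sort_index()
    n = len(counts)
    return pd.DataFrame(
        {
            "n_visits": freq.index.to_numpy(),
            "frequency": freq.to_numpy(),
            "percent": 100 * freq.to_numpy() / n if n else freq.to_numpy(),
        }
    )


def median_iqr(
    counts, method: str = "rounded_rank"
) -> tuple[float, float, float]:
    """Median and quartiles of visit counts.

    ``rounded_rank`` (default) takes the sorted value at rank
    round(q*(n+1)) half away from zero, clipped to [1, n] — the
    convention that reports integer quartiles for integer counts.
    ``linear`` uses numpy's interpolated percentiles.
    """
    x = np.sort(np.asarray(counts if not isinstance(counts, pd.DataFrame) else counts["n_total"]))
    if x.size == 0:
        raise UndefinedEstimateError("median of empty counts")
    if method == "linear":
        q1, q3 = np.percentile(x, [25, 75])
    elif method == "rounded_rank":
        n = x.size

        def _rank(q: float) -> int:
            return int(min(max(round_half_away(q * (n + 1), 0), 1), n))

        q1 = float(x[_rank(0.25) - 1])
        q3 = float(x[_rank(0.75) - 1])
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    return float(np.median(x)), q1, q3


def selfreport_agreement(paired: pd.DataFrame) -> dict[str, float]:
    """Exact / over- / under-report fractions for (reported, chart) pairs.

    ``paired`` needs columns ``reported`` and ``chart``; the three
    fractions sum to 1.
    """
    if len(paired) == 0:
        raise UndefinedEstimateError("no paired self-report/chart counts")
    rep = paired["reported"].to_numpy()
    chart = paired["chart"].to_numpy()
    n = len(paired)
    return {
        "n_pairs": n,
        "agreement": float((rep == chart).sum() / n),
        "over_report": float((rep > chart).sum() / n),
        "under_report": float((rep < chart).sum() / n),
    }
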