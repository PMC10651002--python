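"""End-to-end orchestration, group comparability, and report rendering.

``run_pipeline`` executes the full analysis — exclusion screening, GA
dating, subcohort selection, coverage, retention, LTFU sensitivity
scenarios, and baseline-comparability testing — and writes one tidy CSV
per stage plus a ``run.json`` capturing config, seed, versions and
tallies, sufficient to reproduce the run exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .cohort import (
    ExclusionTally,
    apply_exclusions,
    ltfu_records,
    read_cohort,
    read_visits,
    resolve_anchors,
    select_subcohort,
)
from .coverage import (
    assemble_visit_counts,
    coverage_indicators,
    median_iqr,
    round_half_away,
    selfreport_agreement,
    visit_distribution,
)
from .dating import DEFAULT_DISCREPANCY_LIMIT_DAYS
from .retention import (
    cumulative_retention,
    flow_table,
    sequential_retention,
    assign_windows,
)
from .sensitivity import ScenarioSpec, run_scenarios
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger("anccov")

OUTPUT_FILES = (
    "exclusions.csv",
    "coverage.csv",
    "distribution.csv",
    "retention.csv",
    "flow.csv",
    "sensitivity.csv",
    "comparability.csv",
)

INDICATOR_LABELS = {
    "ge_1": "At least one ANC visit",
    "ge_4": "Four or more ANC visits",
    "ge_8": "Eight or more ANC visits",
    "zero": "No ANC visit",
}

RETENTION_LABELS = {
    "after_anc1": "Retention after ANC 1 (<16 weeks)",
    "after_anc2": "Retention after ANC 2 (16 to <28 weeks)",
    "after_anc3": "Retention after ANC 3 (28 to <36 weeks)",
    "through_anc1": "Retention in ANC 1 (<16 weeks)",
    "through_anc2": "Retention in ANC 1 and ANC 2 (16 to <28 weeks)",
    "through_anc3": "Retention in ANC 1 to ANC 3 (28 to <36 weeks)",
    "through_anc4": "Retention in ANC 1 to ANC 4 (>=36 weeks)",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    cohort_path: Optional[str] = None
    visits_path: Optional[str] = None
    simulate: Optional[SimulationConfig] = None
    subcohort_threshold_weeks: float = 13.0
    coverage_thresholds: tuple[int, ...] = (1, 4, 8)
    level: float = 0.95
    scenario_fs: tuple[float, ...] = (0.0, 0.5, 0.9)
    #: 'subcohort' restricts the LTFU scenarios to women enrolled below
    #: the threshold; 'full' uses the whole analysis population.
    scenario_scope: str = "subcohort"
    quartile_method: str = "rounded_rank"
    discrepancy_limit_days: int = DEFAULT_DISCREPANCY_LIMIT_DAYS
    out_dir: Optional[str] = None
    seed: int = 20181201
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_files = self.cohort_path is not None and self.visits_path is not None
        if not has_files and self.simulate is None:
            raise ValueError("either input paths or a simulate spec is required")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must lie in (0, 1)")
        if self.scenario_scope not in ("subcohort", "full"):
            raise ValueError("scenario_scope must be 'subcohort' or 'full'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            if "study_start" in sim and isinstance(sim["study_start"], str):
                sim["study_start"] = dt.date.fromisoformat(sim["study_start"])
            if "window_attendance_probs" in sim:
                sim["window_attendance_probs"] = tuple(sim["window_attendance_probs"])
            sim = SimulationConfig(**sim)
        for key in ("coverage_thresholds", "scenario_fs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulate=sim, **raw)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["study_start"] = self.simulate.study_start.isoformat()
            out["simulate"] = sim
        return out


@dataclass
class ReportBundle:
    """All computed tables for one run; the renderer formats, never computes."""

    tally: ExclusionTally
    coverage: pd.DataFrame
    distribution: pd.DataFrame
    visit_median_iqr: tuple[float, float, float]
    retention: pd.DataFrame
    flow: pd.DataFrame
    sensitivity: pd.DataFrame
    comparability: pd.DataFrame
    agreement: Optional[dict]
    n_subcohort: int
    config: RunConfig = field(repr=False)


# --------------------------------------------------------------------------
# group comparability

CONTINUOUS_COVARIATES = ["age_years", "walk_minutes"]
CATEGORICAL_COVARIATES = [
    "district",
    "literate",
    "wealth_q",
    "ethnicity",
    "primiparous",
    "hist_stillbirth",
    "hist_preterm",
]


def _fisher_or_chi2(table: np.ndarray) -> tuple[str, float, float, str]:
    """Test selection: Fisher exact for 2x2 with any expected cell < 5,
    else chi-squared (Yates-corrected for 2x2)."""
    expected = stats.contingency.expected_freq(table)
    note = ""
    if table.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(table)
        return "fisher_exact", float(odds), float(p), note
    if (expected < 5).any():
        note = "expected cell < 5; chi-squared approximate"
    correction = table.shape == (2, 2)
    res = stats.chi2_contingency(table, correction=correction)
    return "chi_squared", float(res[0]), float(res[1]), note


def compare_groups(
    cohort: pd.DataFrame, grouping_threshold_weeks: float = 13.0
) -> pd.DataFrame:
    """Baseline comparability between early (<threshold) and later enrollees.

    Continuous covariates are compared with Student's t-test (mean, SD
    reported per group); categoricals with a chi-squared test, replaced
    by Fisher's exact test for 2x2 tables with any expected cell below
    5.  Covariates absent from the table or all-missing are emitted with
    a note and no test.
    """
    if "enroll_ga_weeks" not in cohort.columns:
        raise ValueError("cohort lacks enroll_ga_weeks; run apply_exclusions first")
    below = cohort["enroll_ga_weeks"] < grouping_threshold_weeks
    rows = []
    for var in CONTINUOUS_COVARIATES:
        if var not in cohort.columns or cohort[var].isna().all():
            rows.append({"variable": var, "test": None, "note": "all missing"})
            continue
        a = cohort.loc[below, var].dropna().astype(float)
        b = cohort.loc[~below, var].dropna().astype(float)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {
                "variable": var,
                "test": "t",
                "n_below": len(a),
                "summary_below": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
                "n_above": len(b),
                "summary_above": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
                "statistic": float(t),
                "p_value": float(p),
                "note": "",
            }
        )
    for var in CATEGORICAL_COVARIATES:
        if var not in cohort.columns or cohort[var].isna().all():
            rows.append({"variable": var, "test": None, "note": "all missing"})
            continue
        sub = cohort[[var]].assign(below=below).dropna(subset=[var])
        table = pd.crosstab(sub["below"], sub[var])
        if table.shape[0] < 2 or table.shape[1] < 2:
            rows.append({"variable": var, "test": None, "note": "degenerate table"})
            continue
        arr = table.reindex([True, False]).to_numpy()
        test, stat, p, note = _fisher_or_chi2(arr)
        n_a, n_b = int(arr[0].sum()), int(arr[1].sum())
        rows.append(
            {
                "variable": var,
                "test": test,
                "n_below": n_a,
                "summary_below": "; ".join(
                    f"{c}: {v} ({100 * v / n_a:.1f})" for c, v in zip(table.columns, arr[0])
                ),
                "n_above": n_b,
                "summary_above": "; ".join(
                    f"{c}: {v} ({100 * v / n_b:.1f})" for c, v in zip(table.columns, arr[1])
                ),
                "statistic": stat,
                "p_value": p,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pipeline


def _retro_agreement_pairs(
    cohort: pd.DataFrame, visits: pd.DataFrame
) -> pd.DataFrame:
    """(reported, chart) pairs for women with retrospective chart abstraction."""
    retro = visits[
        (visits["source"] == "chart_retrospective")
        & visits["woman_id"].isin(cohort["woman_id"])
    ].drop_duplicates(subset=["woman_id", "visit_date"])
    if len(retro) == 0:
        return pd.DataFrame(columns=["reported", "chart"])
    chart = retro.groupby("woman_id").size()
    reported = cohort.set_index("woman_id")["self_visits_enroll"].fillna(0).astype(int)
    return pd.DataFrame(
        {"reported": reported.reindex(chart.index).to_numpy(), "chart": chart.to_numpy()}
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute all stages and (if ``out_dir`` is set) write the outputs."""
    logging.basicConfig(level=config.log_level)
    stage = "load"
    try:
        if config.simulate is not None:
            cohort, visits, _truth = simulate_cohort(config.simulate, config.seed)
        else:
            cohort = read_cohort(config.cohort_path)
            visits = read_visits(config.visits_path)
        logger.info("load: %d pregnancies, %d visit rows", len(cohort), len(visits))

        stage = "exclusions"
        analysis, tally = apply_exclusions(
            cohort, visits, discrepancy_limit_days=config.discrepancy_limit_days
        )
        lost = ltfu_records(
            cohort, discrepancy_limit_days=config.discrepancy_limit_days
        )
        logger.info("exclusions: %s", tally.as_dict())

        stage = "subcohort"
        sub = select_subcohort(analysis, config.subcohort_threshold_weeks)
        logger.info("subcohort <%.0f weeks: %d women", config.subcohort_threshold_weeks, len(sub))

        stage = "comparability"
        comparability = compare_groups(analysis, config.subcohort_threshold_weeks)

        stage = "coverage"
        counts = assemble_visit_counts(sub, visits)
        indicators = coverage_indicators(counts, config.coverage_thresholds, config.level)
        coverage_df = pd.DataFrame(
            [
                {"indicator": key, "label": INDICATOR_LABELS.get(key, key), **est.as_row()}
                for key, est in indicators.items()
            ]
        )
        distribution = visit_distribution(counts)
        med = median_iqr(counts, config.quartile_method)
        pairs = _retro_agreement_pairs(analysis, visits)
        agreement = selfreport_agreement(pairs) if len(pairs) else None

        stage = "retention"
        anchors = resolve_anchors(sub, config.discrepancy_limit_days)
        flags = assign_windows(sub, visits, anchors)
        retention_rows = sequential_retention(flags, config.level) + cumulative_retention(
            flags, config.level
        )
        retention_df = pd.DataFrame(
            [
                {"label": r.label, "N": r.denominator, "n": r.numerator, **{
                    k: v for k, v in r.estimate.as_row().items()
                    if k in ("pct", "ci_low", "ci_high")
                }}
                for r in retention_rows
            ]
        )
        flow = flow_table(flags)

        stage = "sensitivity"
        if config.scenario_scope == "subcohort":
            completers = counts
            lost_scope = select_subcohort(lost, config.subcohort_threshold_weeks)
        else:
            completers = assemble_visit_counts(analysis, visits)
            lost_scope = lost
        lost_counts = (
            assemble_visit_counts(lost_scope, visits)
            if len(lost_scope)
            else pd.DataFrame(columns=["woman_id", "n_pre_enrollment_selfreport", "n_prospective", "n_total"])
        )
        specs = [ScenarioSpec("any_visit")] + [
            ScenarioSpec("four_plus", f) for f in config.scenario_fs
        ]
        sensitivity = run_scenarios(completers, lost_counts, specs, config.level)
    except Exception as exc:  # noqa: BLE001 - re-raise with the stage name
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    bundle = ReportBundle(
        tally=tally,
        coverage=coverage_df,
        distribution=distribution,
        visit_median_iqr=med,
        retention=retention_df,
        flow=flow,
        sensitivity=sensitivity,
        comparability=comparability,
        agreement=agreement,
        n_subcohort=len(sub),
        config=config,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([bundle.tally.as_dict()]).to_csv(out / "exclusions.csv", index=False)
    bundle.coverage.to_csv(out / "coverage.csv", index=False)
    bundle.distribution.to_csv(out / "distribution.csv", index=False)
    bundle.retention.to_csv(out / "retention.csv", index=False)
    bundle.flow.to_csv(out / "flow.csv", index=False)
    bundle.sensitivity.to_csv(out / "sensitivity.csv", index=False)
    bundle.comparability.to_csv(out / "comparability.csv", index=False)
    run = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": bundle.config.seed,
        "config": bundle.config.to_jsonable(),
        "tally": bundle.tally.as_dict(),
        "n_subcohort": bundle.n_subcohort,
        "visit_median_iqr": list(bundle.visit_median_iqr),
        "selfreport_agreement": bundle.agreement,
    }
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump(run, fh, indent=2, sort_keys=True)


# --------------------------------------------------------------------------
# rendering


def _fmt_pct(x: float) -> str:
    return f"{round_half_away(x, 1):.1f}"


def _fmt_est_cells(row) -> str:
    return (
        f"{_fmt_pct(row['pct'])} ({_fmt_pct(row['ci_low'])}"
        f"–{_fmt_pct(row['ci_high'])})"
    )


def render_report(bundle: ReportBundle, fmt: str = "markdown") -> str:
    """Render the bundle as a paper-style report (markdown or csv).

    Every number is read from the bundle; nothing is recomputed here.
    """
    if fmt not in ("markdown", "csv"):
        raise ValueError(f"unknown report format {fmt!r}")
    if fmt == "csv":
        parts = []
        for name, df in (
            ("coverage", bundle.coverage),
            ("retention", bundle.retention),
            ("sensitivity", bundle.sensitivity),
        ):
            parts.append(f"# {name}")
            parts.append(df.to_csv(index=False).rstrip())
        return "\n".join(parts) + "\n"

    med, q1, q3 = bundle.visit_median_iqr
    lines = ["# ANC coverage and retention report", ""]
    t = bundle.tally
    lines += [
        "## Exclusions",
        "",
        f"{t.n_input} enrolled; {t.n_miscarriage} miscarriages and "
        f"{t.n_implausible_ga} implausible gestational ages excluded; "
        f"{t.n_ltfu} lost to follow-up; {t.n_analysis} analyzed "
        f"({bundle.n_subcohort} enrolled before the subcohort threshold).",
        "",
        "## ANC coverage",
        "",
        "| ANC outcomes | N | n | % (95% CI) |",
        "|---|---|---|---|",
    ]
    denom = (
        int(bundle.coverage["denominator"].iloc[0]) if len(bundle.coverage) else 0
    )
    lines.append(
        f"| Number of ANC visits | {denom} | median {med:g} | IQR {q1:g}–{q3:g} |"
    )
    for _, row in bundle.coverage.iterrows():
        lines.append(
            f"| {row['label']} | {int(row['denominator'])} | "
            f"{int(row['numerator'])} | {_fmt_est_cells(row)} |"
        )
    lines += ["", "## Retention in ANC", ""]
    if len(bundle.retention):
        lines += ["| ANC retention | N | n | % (95% CI) |", "|---|---|---|---|"]
        for _, row in bundle.retention.iterrows():
            label = RETENTION_LABELS.get(row["label"], row["label"])
            lines.append(
                f"| {label} | {int(row['N'])} | {int(row['n'])} | "
                f"{_fmt_est_cells(row)} |"
            )
    else:
        lines.append("(retention section omitted: no window flags computed)")
    lines += ["", "## Loss-to-follow-up sensitivity scenarios", ""]
    if len(bundle.sensitivity):
        lines += ["| Scenario | f | % (95% CI) |", "|---|---|---|"]
        for _, row in bundle.sensitivity.iterrows():
            lines.append(f"| {row['scenario']} | {row['f']:g} | {_fmt_est_cells(row)} |")
    else:
        lines.append("(no scenarios computed)")
    lines.append("")
    return "\n".join(lines)
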