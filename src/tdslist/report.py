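"""Report rendering: comparison, coverage, approach-summary and diff tables.

Printed conventions, applied uniformly: integer percents are rounded half
away from zero; g/kg bw/day means are printed to one decimal (same rounding
rule); coverage below the threshold is flagged in an explicit boolean
column rather than typography.  Rendering identical inputs is
byte-identical, and every printed integer is re-derivable from the
underlying CSV floats by the stated rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import CoverageReport, ListDiff
from .model import FoodList, RunConfig
from .stats import round_half_away

__all__ = ["ReportBundle", "render_reports", "render_coverage_table",
           "render_comparison_table", "render_approach_summary",
           "render_diff_summary"]


def _pct(x) -> object:
    return round_half_away(100.0 * x) if pd.notna(x) else pd.NA


def _mean1(x) -> object:
    return round_half_away(x, decimals=1) if pd.notna(x) else pd.NA


def render_comparison_table(comparison: pd.DataFrame) -> pd.DataFrame:
    """One row per (main_group, age_group): printed means, percent
    difference, significance flag."""
    out = comparison.copy()
    out["mean_old"] = out["mean_old"].map(_mean1)
    out["mean_new"] = out["mean_new"].map(_mean1)
    out["n_old_weighted"] = out["n_old_weighted"].map(
        lambda x: round_half_away(x) if pd.notna(x) else pd.NA
    )
    out["n_new_weighted"] = out["n_new_weighted"].map(
        lambda x: round_half_away(x) if pd.notna(x) else pd.NA
    )
    return out[
        [
            "main_group", "age_group", "mean_old", "n_old_weighted",
            "n_old_unweighted", "mean_new", "n_new_weighted",
            "n_new_unweighted", "pct_difference", "p_value", "significant",
        ]
    ]


def render_coverage_table(report: CoverageReport) -> pd.DataFrame:
    """Per-cell coverage with integer percent, below-threshold flag, and a
    TOTAL row per survey."""
    cells = report.cells.copy()
    rows = []
    for r in cells.itertuples(index=False):
        rows.append(
            {
                "survey_id": r.survey_id,
                "main_group": r.main_group,
                "age_group": r.age_group,
                "covered_mean": float(r.covered_mean),
                "total_mean": float(r.total_mean),
                "fraction_pct": _pct(r.fraction),
                "below_threshold": bool(
                    r.fraction < report.threshold - 1e-12
                ),
                "feasible": bool(r.feasible),
            }
        )
    for sid in sorted(set(cells["survey_id"])):
        sub = cells.loc[cells["survey_id"] == sid]
        covered, total = sub["covered_mean"].sum(), sub["total_mean"].sum()
        rows.append(
            {
                "survey_id": sid,
                "main_group": "TOTAL",
                "age_group": "ALL",
                "covered_mean": float(covered),
                "total_mean": float(total),
                "fraction_pct": _pct(covered / total),
                "below_threshold": bool(
                    covered / total < report.threshold - 1e-12
                ),
                "feasible": True,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "survey_id", "main_group", "age_group", "covered_mean",
            "total_mean", "fraction_pct", "below_threshold", "feasible",
        ],
    )


def render_approach_summary(
    old_list: FoodList, new_list: FoodList, report: CoverageReport
) -> pd.DataFrame:
    """Per main group: TDS-diet mean per (survey, age group), foods before
    and after, change in n, and the min-max coverage range per survey."""
    cells = report.cells
    before = pd.Series([f.main_group for f in old_list]).value_counts()
    after = pd.Series([f.main_group for f in new_list]).value_counts()
    groups = sorted(set(before.index) | set(after.index) | set(cells["main_group"]))
    surveys = sorted(set(cells["survey_id"]))
    rows = []
    for g in groups:
        row: dict = {"main_group": g}
        sub = cells.loc[cells["main_group"] == g]
        for r in sub.itertuples(index=False):
            row[f"tds_diet_mean[{r.survey_id}:{r.age_group}]"] = _mean1(
                r.covered_mean
            )
        row["foods_before"] = int(before.get(g, 0))
        row["foods_after"] = int(after.get(g, 0))
        row["change_n"] = int(after.get(g, 0)) - int(before.get(g, 0))
        for sid in surveys:
            ss = sub.loc[sub["survey_id"] == sid, "fraction"]
            if len(ss):
                lo, hi = _pct(ss.min()), _pct(ss.max())
                row[f"coverage_range[{sid}]"] = (
                    f"{lo}" if lo == hi else f"{lo}-{hi}"
                )
        rows.append(row)
    total_row: dict = {
        "main_group": "TOTAL",
        "foods_before": len(old_list),
        "foods_after": len(new_list),
        "change_n": len(new_list) - len(old_list),
    }
    for sid in surveys:
        ss = cells.loc[cells["survey_id"] == sid, "fraction"]
        lo, hi = _pct(ss.min()), _pct(ss.max())
        total_row[f"coverage_range[{sid}]"] = f"{lo}" if lo == hi else f"{lo}-{hi}"
    rows.append(total_row)
    return pd.DataFrame(rows)


def render_diff_summary(diff: ListDiff) -> pd.DataFrame:
    """Counts and percentages of the retained/removed/added partition plus
    the origin composition of the new list's additions."""
    n_old, n_new = diff.n_old, diff.n_new
    rows = [
        {
            "item": "retained",
            "count": len(diff.retained),
            "pct": _pct(len(diff.retained) / n_old) if n_old else pd.NA,
            "of": "old list",
        },
        {
            "item": "removed",
            "count": len(diff.removed),
            "pct": _pct(len(diff.removed) / n_old) if n_old else pd.NA,
            "of": "old list",
        },
        {
            "item": "added",
            "count": len(diff.added),
            "pct": _pct(len(diff.added) / n_new) if n_new else pd.NA,
            "of": "new list",
        },
    ]
    for origin, foods in diff.added_by_origin.items():
        rows.append(
            {
                "item": f"added[{origin}]",
                "count": len(foods),
                "pct": _pct(len(foods) / n_new) if n_new else pd.NA,
                "of": "new list",
            }
        )
    return pd.DataFrame(rows, columns=["item", "count", "pct", "of"])


@dataclass
class ReportBundle:
    comparison: pd.DataFrame | None
    coverage: pd.DataFrame
    approach_summary: pd.DataFrame | None
    diff_summary: pd.DataFrame | None

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        tables = {
            "comparison": self.comparison,
            "coverage": self.coverage,
            "approach_summary": self.approach_summary,
            "diff_summary": self.diff_summary,
        }
        for name, df in tables.items():
            if df is not None:
                p = out / f"{name}.csv"
                df.to_csv(p, index=False)
                paths[name] = p
        text = out / "report.txt"
        text.write_text(self.render_text(), encoding="utf-8")
        paths["text"] = text
        return paths

    def render_text(self) -> str:
        parts = []
        for title, df in (
            ("Consumption comparison", self.comparison),
            ("Coverage", self.coverage),
            ("Approach summary", self.approach_summary),
            ("List diff", self.diff_summary),
        ):
            if df is not None:
                parts.append(f"== {title} ==\n{df.to_string(index=False)}\n")
        return "\n".join(parts)


def render_reports(
    config: RunConfig,
    coverage: CoverageReport,
    comparison: pd.DataFrame | None = None,
    old_list: FoodList | None = None,
    new_list: FoodList | None = None,
    diff: ListDiff | None = None,
) -> ReportBundle:
    """Assemble the full report bundle with the fixed rounding conventions.

    Raises when the comparison and coverage tables disagree on the age
    groups they describe (inconsistent inputs).
    """
    if comparison is not None and not coverage.cells.empty:
        cov_groups = set(coverage.cells["age_group"])
        cmp_groups = set(comparison["age_group"])
        if not cmp_groups <= cov_groups | {"ALL"} and not cov_groups <= cmp_groups:
            raise ValueError(
                "comparison and coverage tables use inconsistent age groups: "
                f"{sorted(cmp_groups)} vs {sorted(cov_groups)}"
            )
    return ReportBundle(
        comparison=(
            render_comparison_table(comparison) if comparison is not None else None
        ),
        coverage=render_coverage_table(coverage),
        approach_summary=(
            render_approach_summary(old_list, new_list, coverage)
            if old_list is not None and new_list is not None
            else None
        ),
        diff_summary=render_diff_summary(diff) if diff is not None else None,
    )
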