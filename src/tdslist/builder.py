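"""Food-list compilation, coverage auditing and the three update strategies.

A TDS food list must cover at least a threshold fraction (conventionally
90%) of mean consumption, in g/kg bw/day, within every main food group and
every age group.  The machinery here:

* ``select_min_covering`` — within one (main group x age group) cell, the
  shortest descending-consumption prefix of candidate foods reaching the
  threshold.  Because amounts are non-negative, the greedy prefix is a
  minimum-cardinality covering subset.
* ``audit_coverage`` — strategy 1: apply an existing list unchanged to new
  surveys and report the covered fraction per cell and overall.
* ``extend_list`` — strategy 2: keep the existing list, add residual foods
  to deficient cells until the threshold is met, then prune newly added
  low-consumer-rate foods where coverage permits.
* ``rebuild_list`` — strategy 3: compile a fresh list from the new surveys,
  supplement it with foods carried over for population groups not
  re-surveyed (adults) and with expert-designated extra foods, then prune
  low-consumer-rate consumption-selected foods.
* ``diff_lists`` — retained / removed / added partition between two lists.

Coverage denominators always include consumption on "not further
specified" residual codes, which can never be mapped to a food; a cell
whose unspecified mass alone exceeds 1 - threshold is infeasible and is
reported at its maximum achievable fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import (
    CompositeRule,
    ReconstitutionRule,
    harmonize_records,
    map_records_to_foods,
)
from .model import (
    FoodList,
    RunConfig,
    SurveyDataset,
    TDSFood,
    ORIGIN_CARRIED_ADULT,
    assign_age_group,
    consumption_origin,
)
from .stats import summarize_intake

__all__ = [
    "COVERAGE_TOL",
    "HarmonizedSurvey",
    "SelectionResult",
    "CoverageReport",
    "ListDiff",
    "select_min_covering",
    "residual_candidates",
    "build_initial_list",
    "audit_coverage",
    "extend_list",
    "rebuild_list",
    "diff_lists",
]

#: Absolute tolerance absorbing floating-point summation order in threshold
#: comparisons (covered >= threshold * total - COVERAGE_TOL).
COVERAGE_TOL = 1e-12


# --------------------------------------------------------------------------
# Harmonised survey container


@dataclass
class HarmonizedSurvey:
    """A survey with records already decomposed and reconstituted."""

    survey: SurveyDataset
    records: pd.DataFrame

    @classmethod
    def from_survey(
        cls,
        survey: SurveyDataset,
        composite_rules: Sequence[CompositeRule] = (),
        reconstitution_rules: Sequence[ReconstitutionRule] = (),
    ) -> "HarmonizedSurvey":
        return cls(
            survey=survey,
            records=harmonize_records(
                survey.records, composite_rules, reconstitution_rules
            ),
        )

    def analysis_individuals(self, config: RunConfig) -> pd.DataFrame:
        """Analysis population with a ``stratum`` column (age group, or
        age group x sex when configured)."""
        ind = self.survey.analysis_individuals(config).copy()
        age_label = assign_age_group(ind["age"], config.age_groups)
        if config.stratify_by_sex:
            ind["stratum"] = age_label + "|" + ind["sex"].astype(str)
            ind.loc[age_label.isna(), "stratum"] = pd.NA
        else:
            ind["stratum"] = age_label
        return ind


# --------------------------------------------------------------------------
# Greedy minimal covering selection


@dataclass(frozen=True)
class SelectionResult:
    selected: tuple[str, ...]
    fraction: float
    feasible: bool


def select_min_covering(
    candidates: Mapping[str, float],
    threshold: float,
    total_mean: float | None = None,
) -> SelectionResult:
    """Shortest descending-sorted prefix of candidates covering the threshold.

    ``candidates`` maps food keys to their all-individuals mean consumption
    within one (main group x age group) cell.  ``total_mean`` is the cell's
    full mean including unselectable (unspecified) mass; it defaults to the
    candidate sum.  Ties in mean are broken lexicographically by key.  If no
    prefix reaches ``threshold * total_mean``, every candidate with positive
    mean is returned and the result is flagged infeasible.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if any(v < 0 for v in candidates.values()):
        raise ValueError("candidate means must be >= 0")
    total = sum(candidates.values()) if total_mean is None else total_mean
    if total <= 0:
        return SelectionResult((), 1.0, True)
    target = threshold * total
    order = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    selected: list[str] = []
    cum = 0.0
    for key, mean in order:
        if mean <= 0:
            break  # zero-mean candidates cannot raise coverage
        selected.append(key)
        cum += mean
        if cum >= target - COVERAGE_TOL:
            return SelectionResult(tuple(selected), cum / total, True)
    return SelectionResult(tuple(selected), cum / total, False)


# --------------------------------------------------------------------------
# Candidate universes and the cell-level coverage context


def residual_candidates(
    survey: SurveyDataset, covered_codes: Iterable[str], id_prefix: str = ""
) -> dict[str, TDSFood]:
    """One candidate TDS food per non-unspecified catalogue code not yet
    covered by a list — the default aggregation scheme for new foods."""
    covered = set(covered_codes)
    out: dict[str, TDSFood] = {}
    for row in survey.catalogue.table.itertuples(index=False):
        if row.is_unspecified or row.food_code in covered:
            continue
        fid = f"{id_prefix}{row.food_code}"
        out[fid] = TDSFood(
            id=fid,
            name=row.label,
            main_group=row.main_group,
            member_codes=frozenset([row.food_code]),
        )
    return out


Cell = tuple[str, str, str]  # (survey_id, stratum, main_group)


@dataclass
class _CoverageContext:
    """Per-cell totals and per-food contributions over a candidate universe.

    total[cell]          mean consumption, everything included
    unspecified[cell]    mean consumption on is_unspecified codes
    contrib[cell][food]  mean consumption attributable to each universe food
    rates[food][(survey, stratum)]  weighted consumer rate of the food
    max_mean[food]       largest contribution across all cells (pruning order)
    """

    universe: dict[str, TDSFood]
    total: dict[Cell, float] = field(default_factory=dict)
    unspecified: dict[Cell, float] = field(default_factory=dict)
    contrib: dict[Cell, dict[str, float]] = field(default_factory=dict)
    rates: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)

    @property
    def cells(self) -> list[Cell]:
        return sorted(c for c, t in self.total.items() if t > 0)

    def max_possible(self, cell: Cell) -> float:
        return self.total[cell] - self.unspecified.get(cell, 0.0)

    def covered(self, cell: Cell, food_ids: Iterable[str]) -> float:
        c = self.contrib.get(cell, {})
        return sum(c.get(f, 0.0) for f in food_ids)

    def max_mean(self, food_id: str) -> float:
        return max(
            (c.get(food_id, 0.0) for c in self.contrib.values()), default=0.0
        )

    def max_rate(self, food_id: str) -> float:
        return max(self.rates.get(food_id, {}).values(), default=0.0)


def _build_context(
    surveys: Sequence[HarmonizedSurvey],
    universe: dict[str, TDSFood],
    config: RunConfig,
) -> _CoverageContext:
    ctx = _CoverageContext(universe=universe)
    probe_list = FoodList(version="_universe", foods=list(universe.values()))
    food_group = {f.id: f.main_group for f in universe.values()}
    for hs in surveys:
        sid = hs.survey.survey_id
        ind = hs.analysis_individuals(config)
        ind = ind.dropna(subset=["stratum"])
        if ind.empty:
            continue
        rec = hs.records.loc[hs.records["individual_id"].isin(ind["id"])]

        code_to_group = hs.survey.catalogue.code_to_group()
        all_rec = rec.copy()
        all_rec["main_group"] = all_rec["food_code"].map(code_to_group)
        totals = summarize_intake(all_rec, ind, "main_group")
        for r in totals.itertuples(index=False):
            ctx.total[(sid, r.stratum, r.main_group)] = r.mean_all

        unspec_codes = hs.survey.catalogue.unspecified_codes
        unspec = all_rec.loc[all_rec["food_code"].isin(unspec_codes)]
        if not unspec.empty:
            u = summarize_intake(unspec, ind, "main_group")
            for r in u.itertuples(index=False):
                ctx.unspecified[(sid, r.stratum, r.main_group)] = r.mean_all

        mapped, _ = map_records_to_foods(rec, probe_list)
        if mapped.empty:
            continue
        summary = summarize_intake(mapped, ind, "tds_food_id")
        for r in summary.itertuples(index=False):
            cell = (sid, r.stratum, food_group[r.tds_food_id])
            ctx.contrib.setdefault(cell, {})[r.tds_food_id] = r.mean_all
            ctx.rates.setdefault(r.tds_food_id, {})[(sid, r.stratum)] = (
                r.consumer_rate
            )
    return ctx


# --------------------------------------------------------------------------
# Coverage report


@dataclass
class CoverageReport:
    """Covered fraction per (survey, main group, age group) and per survey.

    ``cells`` columns: survey_id, main_group, age_group, covered_mean,
    total_mean, fraction, max_fraction, feasible.  ``overall`` maps each
    survey id (plus "ALL") to its consumption-weighted total fraction
    sum(covered) / sum(total).
    """

    cells: pd.DataFrame
    overall: dict[str, float]
    threshold: float

    def fraction(self, survey_id: str, main_group: str, age_group: str) -> float:
        m = self.cells
        row = m.loc[
            (m["survey_id"] == survey_id)
            & (m["main_group"] == main_group)
            & (m["age_group"] == age_group)
        ]
        if row.empty:
            raise KeyError((survey_id, main_group, age_group))
        return float(row["fraction"].iloc[0])

    def deficient_cells(self) -> pd.DataFrame:
        return self.cells.loc[
            self.cells["fraction"] < self.threshold - COVERAGE_TOL
        ]


def _report_from_context(
    ctx: _CoverageContext, food_ids: Iterable[str], config: RunConfig
) -> CoverageReport:
    food_ids = list(food_ids)
    rows = []
    for cell in ctx.cells:
        sid, stratum, mg = cell
        total = ctx.total[cell]
        covered = ctx.covered(cell, food_ids)
        max_possible = ctx.max_possible(cell)
        rows.append(
            {
                "survey_id": sid,
                "main_group": mg,
                "age_group": stratum,
                "covered_mean": covered,
                "total_mean": total,
                "fraction": covered / total,
                "max_fraction": max_possible / total,
                "feasible": max_possible
                >= config.coverage_threshold * total - COVERAGE_TOL,
            }
        )
    cells = pd.DataFrame(
        rows,
        columns=[
            "survey_id", "main_group", "age_group", "covered_mean",
            "total_mean", "fraction", "max_fraction", "feasible",
        ],
    )
    overall: dict[str, float] = {}
    if not cells.empty:
        for sid, sub in cells.groupby("survey_id"):
            overall[str(sid)] = float(
                sub["covered_mean"].sum() / sub["total_mean"].sum()
            )
        overall["ALL"] = float(
            cells["covered_mean"].sum() / cells["total_mean"].sum()
        )
    return CoverageReport(
        cells=cells, overall=overall, threshold=config.coverage_threshold
    )


def audit_coverage(
    food_list: FoodList,
    surveys: HarmonizedSurvey | Sequence[HarmonizedSurvey],
    config: RunConfig,
) -> CoverageReport:
    """Strategy 1: apply an existing list unchanged and audit its coverage."""
    if isinstance(surveys, HarmonizedSurvey):
        surveys = [surveys]
    universe = {f.id: f for f in food_list}
    ctx = _build_context(surveys, universe, config)
    return _report_from_context(ctx, universe.keys(), config)


# --------------------------------------------------------------------------
# Initial compilation (the 2016-style build)


def build_initial_list(
    surveys: Sequence[HarmonizedSurvey],
    config: RunConfig,
    template: FoodList | None = None,
    version: str = "initial",
    include_extra: bool = True,
) -> FoodList:
    """Compile a food list from scratch by per-cell greedy selection.

    Candidates are the template's foods (when given — the aggregation scheme
    of an existing list) plus one food per remaining non-unspecified
    catalogue code.  For every (survey, age group, main food group) cell the
    minimum descending-consumption prefix covering the threshold is
    selected; the union over cells, tagged with the demographic groups that
    required each food, plus the configured extra (risk-assessment / trend)
    foods, forms the list.
    """
    universe: dict[str, TDSFood] = {}
    covered_codes: set[str] = set()
    if template is not None:
        for f in template:
            universe[f.id] = TDSFood(
                id=f.id, name=f.name, main_group=f.main_group,
                member_codes=f.member_codes,
            )
            covered_codes |= set(f.member_codes)
    for hs in surveys:
        universe.update(
            residual_candidates(hs.survey, covered_codes | set(universe))
        )
    ctx = _build_context(surveys, universe, config)

    origins: dict[str, set[str]] = {}
    for cell in ctx.cells:
        sid, stratum, mg = cell
        cand = {
            fid: mean
            for fid, mean in ctx.contrib.get(cell, {}).items()
            if not config.consumers_only_filter
            or ctx.rates.get(fid, {}).get((sid, stratum), 0.0)
            >= config.consumer_rate_cutoff
        }
        res = select_min_covering(
            cand, config.coverage_threshold, total_mean=ctx.total[cell]
        )
        for fid in res.selected:
            origins.setdefault(fid, set()).add(consumption_origin(sid, stratum))

    foods = [
        universe[fid].with_origin(*tags) for fid, tags in sorted(origins.items())
    ]
    if include_extra:
        chosen = set(origins)
        for extra in config.extra_foods:
            if extra.id not in chosen:
                foods.append(extra)
    foods.sort(key=lambda f: (f.main_group, f.id))
    return FoodList(version=version, foods=foods)


# --------------------------------------------------------------------------
# List diff


@dataclass
class ListDiff:
    """Retained / removed / added partition between two food lists."""

    retained: tuple[str, ...]
    removed: tuple[str, ...]
    added: tuple[str, ...]
    added_by_origin: dict[str, tuple[str, ...]]

    @property
    def n_old(self) -> int:
        return len(self.retained) + len(self.removed)

    @property
    def n_new(self) -> int:
        return len(self.retained) + len(self.added)


def _origin_category(food: TDSFood) -> str:
    surveys = sorted(
        {t.split(":")[1] for t in food.origin if t.startswith("consumption:")}
    )
    if surveys:
        return "+".join(surveys)
    non_consumption = sorted(food.origin)
    return non_consumption[0] if non_consumption else "unattributed"


def diff_lists(old: FoodList, new: FoodList) -> ListDiff:
    old_ids = set(old.ids)
    new_ids = set(new.ids)
    retained = tuple(sorted(old_ids & new_ids))
    removed = tuple(sorted(old_ids - new_ids))
    added = tuple(sorted(new_ids - old_ids))
    by_origin: dict[str, list[str]] = {}
    for fid in added:
        by_origin.setdefault(_origin_category(new.get(fid)), []).append(fid)
    return ListDiff(
        retained=retained,
        removed=removed,
        added=added,
        added_by_origin={k: tuple(v) for k, v in sorted(by_origin.items())},
    )


# --------------------------------------------------------------------------
# Pruning shared by strategies 2 and 3


def _prune_low_consumer_foods(
    ctx: _CoverageContext,
    selected: list[str],
    prunable: set[str],
    config: RunConfig,
) -> list[str]:
    """Greedily drop prunable foods with consumer rate below the cutoff in
    every demographic group, least-consumed first, whenever every cell stays
    at >= threshold (or, for infeasible cells, at its achievable maximum)."""
    cells = ctx.cells
    required = {
        cell: min(
            config.coverage_threshold * ctx.total[cell], ctx.max_possible(cell)
        )
        for cell in cells
    }
    covered = {cell: ctx.covered(cell, selected) for cell in cells}
    candidates = sorted(
        (f for f in prunable if ctx.max_rate(f) < config.consumer_rate_cutoff),
        key=lambda f: (ctx.max_mean(f), f),
    )
    kept = list(selected)
    for fid in candidates:
        ok = True
        for cell in cells:
            c = ctx.contrib.get(cell, {}).get(fid, 0.0)
            if c and covered[cell] - c < required[cell] - COVERAGE_TOL:
                ok = False
                break
        if ok:
            kept.remove(fid)
            for cell in cells:
                c = ctx.contrib.get(cell, {}).get(fid, 0.0)
                if c:
                    covered[cell] -= c
    return kept


# --------------------------------------------------------------------------
# Strategy 2: constrained extension of an existing list


def extend_list(
    food_list: FoodList,
    surveys: Sequence[HarmonizedSurvey],
    config: RunConfig,
    version: str | None = None,
) -> tuple[FoodList, CoverageReport, ListDiff]:
    """Keep the existing list; add residual foods to deficient cells, then
    prune low-consumer additions.

    For every cell below the coverage threshold, residual candidate foods
    are added in descending mean-consumption order until the cell reaches
    the threshold or exhausts its candidates (infeasible).  Foods of the
    original list are never removed; among the newly added foods, those with
    a consumer rate below the cutoff in every demographic group are removed
    greedily, least-consumed first, whenever coverage permits.
    """
    covered_codes = {c for f in food_list for c in f.member_codes}
    universe = {f.id: f for f in food_list}
    residual = {}
    for hs in surveys:
        residual.update(
            residual_candidates(hs.survey, covered_codes | set(universe))
        )
    universe.update(residual)
    ctx = _build_context(surveys, universe, config)

    original = list(food_list.ids)
    added_origins: dict[str, set[str]] = {}
    covered = {cell: ctx.covered(cell, original) for cell in ctx.cells}
    current_added: list[str] = []
    for cell in ctx.cells:
        sid, stratum, mg = cell
        target = config.coverage_threshold * ctx.total[cell]
        if covered[cell] >= target - COVERAGE_TOL:
            continue
        cand = {
            fid: mean
            for fid, mean in ctx.contrib.get(cell, {}).items()
            if fid in residual and mean > 0
        }
        if config.consumers_only_filter:
            cand = {
                fid: mean
                for fid, mean in cand.items()
                if ctx.rates.get(fid, {}).get((sid, stratum), 0.0)
                >= config.consumer_rate_cutoff
            }
        # descending mean, ties lexicographic — same ordering as selection
        for fid, mean in sorted(cand.items(), key=lambda kv: (-kv[1], kv[0])):
            already = fid in added_origins
            added_origins.setdefault(fid, set()).add(
                consumption_origin(sid, stratum)
            )
            if not already:
                current_added.append(fid)
                for c2 in ctx.cells:
                    contrib = ctx.contrib.get(c2, {}).get(fid, 0.0)
                    if contrib:
                        covered[c2] += contrib
            if covered[cell] >= target - COVERAGE_TOL:
                break

    all_selected = original + sorted(current_added)
    kept = _prune_low_consumer_foods(
        ctx, all_selected, set(current_added), config
    )
    kept_added = [f for f in kept if f not in set(original)]

    foods = list(food_list.foods) + [
        universe[fid].with_origin(*added_origins[fid]) for fid in sorted(kept_added)
    ]
    new_list = FoodList(
        version=version or f"{food_list.version}+extended", foods=foods
    )
    report = _report_from_context(ctx, new_list.ids, config)
    return new_list, report, diff_lists(food_list, new_list)


# --------------------------------------------------------------------------
# Strategy 3: independent rebuild with carry-over and merge


def rebuild_list(
    old_list: FoodList,
    surveys: Sequence[HarmonizedSurvey],
    config: RunConfig,
    carried_over: Sequence[TDSFood] = (),
    version: str = "rebuilt",
) -> tuple[FoodList, CoverageReport, ListDiff]:
    """Compile a fresh list from the new surveys and merge with carry-overs.

    The fresh build uses the old list's foods as the aggregation template
    (plus per-code candidates for everything the old list does not cover),
    so the diff against the old list is meaningful food-by-food.  Foods
    carried over for population groups without new data (tagged as adult
    carry-overs) and configured extra foods are merged in; consumer-rate
    pruning then applies to all consumption-selected foods — but never to
    carry-overs or extra foods.
    """
    fresh = build_initial_list(
        surveys, config, template=old_list, version=version, include_extra=False
    )
    carried_ids = {f.id for f in carried_over}
    extra_ids = {f.id for f in config.extra_foods}

    merged: dict[str, TDSFood] = {f.id: f for f in fresh}
    for f in carried_over:
        if f.id in merged:
            merged[f.id] = merged[f.id].with_origin(ORIGIN_CARRIED_ADULT)
        else:
            merged[f.id] = f.with_origin(ORIGIN_CARRIED_ADULT)
    for f in config.extra_foods:
        if f.id not in merged:
            merged[f.id] = f

    # context over everything that could contribute coverage
    covered_codes: set[str] = set()
    universe: dict[str, TDSFood] = {}
    for f in old_list:
        universe[f.id] = f
        covered_codes |= set(f.member_codes)
    for f in merged.values():
        if f.id not in universe:
            universe[f.id] = f
            covered_codes |= set(f.member_codes)
    for hs in surveys:
        universe.update(
            residual_candidates(hs.survey, covered_codes | set(universe))
        )
    ctx = _build_context(surveys, universe, config)

    selected = sorted(merged)
    prunable = {
        fid for fid in selected if fid not in carried_ids and fid not in extra_ids
    }
    kept = _prune_low_consumer_foods(ctx, selected, prunable, config)

    foods = sorted(
        (merged[fid] for fid in kept), key=lambda f: (f.main_group, f.id)
    )
    new_list = FoodList(version=version, foods=foods)
    report = _report_from_context(ctx, new_list.ids, config)
    return new_list, report, diff_lists(old_list, new_list)
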