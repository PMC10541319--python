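"""Harmonisation of raw consumption records onto TDS foods.

Raw dietary records arrive coded on a detailed catalogue and in the state
recorded, not the state eaten.  Three transformations, applied in a fixed
order, turn them into records on TDS foods:

1. composite decomposition — dishes combining components from several main
   food groups (pasta with tomato sauce) are split into their components by
   fixed gram proportions;
2. reconstitution — records of concentrates/powders are rescaled to the
   "as consumed" form (instant tea powder -> prepared tea beverage);
3. mapping — each record whose code is a member of a TDS food is assigned to
   that food; everything else, including "not further specified" residual
   codes, stays in an explicit unmapped residual.

Grams are conserved through steps 1 and 3; step 2 rescales by the declared
reconstitution factor exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import FoodList, SurveyDataset, ValidationError

__all__ = [
    "CompositeRule",
    "ReconstitutionRule",
    "read_composite_rules",
    "read_reconstitution_rules",
    "write_composite_rules",
    "decompose_composites",
    "apply_reconstitution",
    "map_records_to_foods",
    "harmonize_records",
]

_PROPORTION_TOL = 1e-9


@dataclass(frozen=True)
class CompositeRule:
    """Break one composite code into (component code, gram proportion) parts."""

    composite_code: str
    components: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValidationError(
                f"composite rule {self.composite_code!r} has no components"
            )
        props = [p for _, p in self.components]
        if any(p <= 0 for p in props):
            raise ValidationError(
                f"composite rule {self.composite_code!r}: proportions must be > 0"
            )
        if abs(sum(props) - 1.0) > _PROPORTION_TOL:
            raise ValidationError(
                f"composite rule {self.composite_code!r}: proportions sum to "
                f"{sum(props)!r}, expected 1"
            )


@dataclass(frozen=True)
class ReconstitutionRule:
    """Re-code raw_code to target_code scaling grams by amount_factor."""

    raw_code: str
    target_code: str
    amount_factor: float

    def __post_init__(self) -> None:
        if self.amount_factor <= 0:
            raise ValidationError(
                f"reconstitution rule {self.raw_code!r}: amount_factor must be > 0"
            )


def _check_unique_rules(codes: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for c in codes:
        if c in seen:
            raise ValidationError(f"multiple {what} rules for code {c!r}")
        seen.add(c)


def read_composite_rules(path: str | Path) -> list[CompositeRule]:
    df = pd.read_csv(path, dtype={"composite_code": str, "component_code": str})
    rules = [
        CompositeRule(
            composite_code=code,
            components=tuple(
                (r.component_code, float(r.proportion))
                for r in grp.itertuples(index=False)
            ),
        )
        for code, grp in df.groupby("composite_code", sort=True)
    ]
    return rules


def write_composite_rules(rules: Sequence[CompositeRule], path: str | Path) -> Path:
    rows = [
        {"composite_code": r.composite_code, "component_code": c, "proportion": p}
        for r in rules
        for c, p in r.components
    ]
    path = Path(path)
    pd.DataFrame(rows, columns=["composite_code", "component_code", "proportion"]).to_csv(
        path, index=False
    )
    return path


def read_reconstitution_rules(path: str | Path) -> list[ReconstitutionRule]:
    df = pd.read_csv(path, dtype={"raw_code": str, "target_code": str})
    return [
        ReconstitutionRule(r.raw_code, r.target_code, float(r.amount_factor))
        for r in df.itertuples(index=False)
    ]


def decompose_composites(
    records: pd.DataFrame, rules: Sequence[CompositeRule]
) -> pd.DataFrame:
    """Replace each composite record by one record per component.

    Component amounts are parent amount x proportion on the same individual
    and day, so grams per (individual, day) are conserved.  One level only:
    a rule whose component code itself has a rule is a configuration error.
    """
    _check_unique_rules([r.composite_code for r in rules], "composite")
    rule_codes = {r.composite_code for r in rules}
    for r in rules:
        nested = [c for c, _ in r.components if c in rule_codes]
        if nested:
            raise ValidationError(
                f"composite rule {r.composite_code!r} has composite component(s) "
                f"{nested}; only one level of decomposition is supported"
            )
    if not rules or records.empty:
        return records.copy()

    is_composite = records["food_code"].isin(rule_codes)
    passthrough = records.loc[~is_composite]
    matched = records.loc[is_composite]
    if matched.empty:
        return records.copy()

    expansion = pd.DataFrame(
        [
            {"food_code": r.composite_code, "component_code": c, "proportion": p}
            for r in rules
            for c, p in r.components
        ]
    )
    exploded = matched.merge(expansion, on="food_code", how="left")
    exploded["amount_g"] = exploded["amount_g"] * exploded["proportion"]
    exploded = exploded.drop(columns=["food_code", "proportion"]).rename(
        columns={"component_code": "food_code"}
    )
    out = pd.concat(
        [passthrough, exploded[records.columns]], ignore_index=True
    )
    return out


def apply_reconstitution(
    records: pd.DataFrame, rules: Sequence[ReconstitutionRule]
) -> pd.DataFrame:
    """Re-code matched records to their as-consumed form, scaling amounts."""
    _check_unique_rules([r.raw_code for r in rules], "reconstitution")
    if not rules or records.empty:
        return records.copy()
    target = {r.raw_code: r.target_code for r in rules}
    factor = {r.raw_code: r.amount_factor for r in rules}
    out = records.copy()
    matched = out["food_code"].isin(target)
    out.loc[matched, "amount_g"] = out.loc[matched, "amount_g"] * out.loc[
        matched, "food_code"
    ].map(factor)
    out.loc[matched, "food_code"] = out.loc[matched, "food_code"].map(target)
    return out


def map_records_to_foods(
    records: pd.DataFrame, food_list: FoodList
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition records into (mapped onto TDS foods, unmapped residual).

    mapped has columns individual_id, day, tds_food_id, amount_g; residual
    keeps the raw record columns.  Grams are conserved across the partition:
    mapped grams + residual grams = input grams.
    """
    code_to_food = food_list.code_to_food()
    assigned = records["food_code"].map(code_to_food)
    mapped = records.loc[assigned.notna()].copy()
    mapped["tds_food_id"] = assigned[assigned.notna()]
    mapped = mapped[["individual_id", "day", "tds_food_id", "amount_g"]]
    residual = records.loc[assigned.isna()].copy()
    return mapped.reset_index(drop=True), residual.reset_index(drop=True)


def harmonize_records(
    records: pd.DataFrame,
    composite_rules: Sequence[CompositeRule] = (),
    reconstitution_rules: Sequence[ReconstitutionRule] = (),
) -> pd.DataFrame:
    """Composites first, then reconstitution: a dish component may itself
    need reconstitution."""
    out = decompose_composites(records, composite_rules)
    out = apply_reconstitution(out, reconstitution_rules)
    return out
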