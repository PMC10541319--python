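"""Synthetic dietary surveys with planted, recoverable structure.

The real German surveys behind TDS food lists (dietary records of
individuals with ages, body weights and calibration weights, coded on a
19-main-group food catalogue) are not publicly distributable, so every
pipeline stage is exercised on generated surveys that emulate their shape:

* individuals with age, sex, body weight and sampling weight, reporting
  over a small number of days (three plus one is the survey convention);
* zero-inflated, right-skewed daily amounts: each individual is a consumer
  of a food with a planted probability, consumers eat on any given day with
  a day-level probability, and positive amounts are log-normal;
* a configurable fraction of records emitted as composite-dish codes (with
  matching decomposition rules) and of each main group's mass emitted on
  unmappable "not further specified" codes.

``generate_planted_scenario`` additionally builds tiny survey/list pairs
whose correct outcome (minimal cover, food that must be added, food that
must be pruned, infeasible cell's maximum fraction, or list diff) is
computed inside the generator by independent closed-form/brute-force
arithmetic — never by the pipeline under test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .harmonize import CompositeRule
from .model import (
    AgeGroup,
    FoodCatalogue,
    FoodList,
    RunConfig,
    SurveyDataset,
    TDSFood,
)

__all__ = [
    "MAIN_GROUPS",
    "FoodSpec",
    "AgeGroupSpec",
    "GeneratorConfig",
    "default_generator_config",
    "generate_survey",
    "PlantedScenario",
    "generate_planted_scenario",
    "expected_observed_consumer_rate",
    "expected_consumers_only_mean",
]

#: The 19 top-level food groups partitioning the catalogue.
MAIN_GROUPS = [
    "Grains and grain-based products",
    "Vegetables and vegetable products",
    "Starchy roots or tubers and products thereof",
    "Legumes, nuts, oilseeds and spices",
    "Fruit and fruit products",
    "Meat and meat products",
    "Fish, seafood and invertebrates",
    "Milk and dairy products",
    "Eggs and egg products",
    "Sugar, confectionery and water-based sweet desserts",
    "Animal and vegetable fats and oils",
    "Fruit and vegetable juices and nectars",
    "Water and water-based beverages",
    "Coffee, cocoa, tea and infusions",
    "Alcoholic beverages",
    "Food products for infants and toddlers",
    "Products for non-standard diets and food imitates",
    "Composite dishes",
    "Seasoning, sauces and condiments",
]

_COMPOSITE_GROUP = "Composite dishes"


class FoodSpec(BaseModel):
    """One food's planted consumption process."""

    code: str
    label: str
    main_group: str
    consumer_probability: float = Field(ge=0, le=1)
    meanlog: float  # log-gram scale of the per-day amount
    sdlog: float = Field(gt=0)
    day_probability: float = Field(default=1.0, ge=0, le=1)


class AgeGroupSpec(BaseModel):
    """Population of one age group."""

    label: str
    lower: float = Field(ge=0)
    upper: float
    n_individuals: int = Field(ge=1)
    body_weight_mean: float = Field(gt=0)
    body_weight_sd: float = Field(default=0.0, ge=0)
    sampling_weight_sdlog: float = Field(default=0.3, ge=0)


class GeneratorConfig(BaseModel):
    survey_id: str = "synthetic"
    foods: list[FoodSpec]
    age_groups: list[AgeGroupSpec]
    n_reporting_days: int = Field(default=4, ge=1)
    fraction_composite: float = Field(default=0.0, ge=0, le=1)
    fraction_unspecified: float = Field(default=0.0, ge=0, le=1)
    breastfed_fraction: float = Field(default=0.0, ge=0, le=1)
    seed: int = 0

    def age_group_labels(self) -> list[AgeGroup]:
        return [
            AgeGroup(label=g.label, lower=g.lower, upper=g.upper)
            for g in self.age_groups
        ]


def _unspecified_code(main_group: str) -> str:
    # initials keep the code unique across the 19 group labels
    initials = "".join(w[0] for w in main_group.split()).upper()
    return f"{initials}.NFS"


def default_generator_config(
    seed: int = 0,
    n_individuals: int = 120,
    n_foods_per_group: tuple[int, int] = (5, 30),
    survey_id: str = "synthetic",
) -> GeneratorConfig:
    """A survey resembling a child dietary record study: 19 main groups with
    5-30 foods each, three age groups, four reporting days."""
    rng = np.random.default_rng(seed)
    foods: list[FoodSpec] = []
    for gi, group in enumerate(MAIN_GROUPS):
        n_foods = int(rng.integers(n_foods_per_group[0], n_foods_per_group[1] + 1))
        for fi in range(n_foods):
            foods.append(
                FoodSpec(
                    code=f"G{gi:02d}.{fi:03d}",
                    label=f"{group} food {fi}",
                    main_group=group,
                    # few popular foods, many rare ones (right-skewed ranks)
                    consumer_probability=float(
                        np.clip(rng.beta(0.8, 3.0), 0.005, 0.95)
                    ),
                    meanlog=float(rng.uniform(1.5, 4.5)),
                    sdlog=float(rng.uniform(0.4, 1.0)),
                    day_probability=float(rng.uniform(0.3, 1.0)),
                )
            )
    age_groups = [
        AgeGroupSpec(
            label="0.5-<1 y", lower=0.5, upper=1.0,
            n_individuals=max(1, n_individuals // 4),
            body_weight_mean=8.5, body_weight_sd=1.0,
        ),
        AgeGroupSpec(
            label="1-<3 y", lower=1.0, upper=3.0,
            n_individuals=n_individuals,
            body_weight_mean=12.0, body_weight_sd=2.0,
        ),
        AgeGroupSpec(
            label="3-<6 y", lower=3.0, upper=6.0,
            n_individuals=n_individuals,
            body_weight_mean=18.0, body_weight_sd=3.0,
        ),
    ]
    return GeneratorConfig(
        survey_id=survey_id,
        foods=foods,
        age_groups=age_groups,
        fraction_composite=0.05,
        fraction_unspecified=0.03,
        seed=seed,
    )


def _build_catalogue(config: GeneratorConfig) -> tuple[pd.DataFrame, list[CompositeRule]]:
    rows = [
        {
            "food_code": f.code,
            "label": f.label,
            "main_group": f.main_group,
            "is_unspecified": False,
        }
        for f in config.foods
    ]
    groups = {f.main_group for f in config.foods}
    for g in sorted(groups):
        rows.append(
            {
                "food_code": _unspecified_code(g),
                "label": f"Not further specified {g.lower()}",
                "main_group": g,
                "is_unspecified": True,
            }
        )
    rules: list[CompositeRule] = []
    if config.fraction_composite > 0:
        specs = config.foods
        for i, f in enumerate(specs):
            partner = specs[(i + 1) % len(specs)]
            if partner.main_group == f.main_group or f.main_group == _COMPOSITE_GROUP:
                continue
            code = f"CD.{f.code}"
            rows.append(
                {
                    "food_code": code,
                    "label": f"Dish of {f.label} with {partner.label}",
                    "main_group": _COMPOSITE_GROUP,
                    "is_unspecified": False,
                }
            )
            rules.append(
                CompositeRule(
                    composite_code=code,
                    components=((f.code, 0.6), (partner.code, 0.4)),
                )
            )
    catalogue = pd.DataFrame(
        rows, columns=["food_code", "label", "main_group", "is_unspecified"]
    )
    return catalogue, rules


def generate_survey(
    config: GeneratorConfig,
) -> tuple[SurveyDataset, list[CompositeRule]]:
    """Draw one survey; reproducible given the config seed.

    Returns the dataset together with the decomposition rules for the
    composite codes it emitted (empty when fraction_composite is zero).
    """
    rng = np.random.default_rng(config.seed)
    catalogue_df, composite_rules = _build_catalogue(config)
    composite_of = {r.components[0][0]: r for r in composite_rules}

    ind_rows = []
    for g in config.age_groups:
        for i in range(g.n_individuals):
            ind_id = f"{config.survey_id}-{g.label}-{i:05d}"
            bw = float(
                np.clip(
                    rng.normal(g.body_weight_mean, g.body_weight_sd),
                    0.2 * g.body_weight_mean,
                    None,
                )
            )
            ind_rows.append(
                {
                    "id": ind_id,
                    "survey_id": config.survey_id,
                    "age": float(rng.uniform(g.lower, g.upper)),
                    "sex": str(rng.choice(["f", "m"])),
                    "body_weight": bw,
                    "sampling_weight": float(
                        rng.lognormal(0.0, g.sampling_weight_sdlog)
                    )
                    if g.sampling_weight_sdlog > 0
                    else 1.0,
                    "n_reporting_days": config.n_reporting_days,
                    "breastfed": bool(rng.random() < config.breastfed_fraction),
                }
            )
    individuals = pd.DataFrame(ind_rows)

    rec_rows = []
    n_days = config.n_reporting_days
    ids = individuals["id"].to_numpy()
    n_ind = len(ids)
    for f in config.foods:
        is_consumer = rng.random(n_ind) < f.consumer_probability
        for idx in np.nonzero(is_consumer)[0]:
            eats = rng.random(n_days) < f.day_probability
            if not eats.any():
                continue
            amounts = rng.lognormal(f.meanlog, f.sdlog, size=int(eats.sum()))
            for day, amount in zip(np.nonzero(eats)[0] + 1, amounts):
                code = f.code
                if (
                    config.fraction_unspecified > 0
                    and rng.random() < config.fraction_unspecified
                ):
                    code = _unspecified_code(f.main_group)
                elif (
                    f.code in composite_of
                    and rng.random() < config.fraction_composite
                ):
                    rule = composite_of[f.code]
                    code = rule.composite_code
                    amount = amount / rule.components[0][1]
                rec_rows.append(
                    {
                        "individual_id": ids[idx],
                        "day": int(day),
                        "food_code": code,
                        "amount_g": float(amount),
                    }
                )
    records = pd.DataFrame(
        rec_rows, columns=["individual_id", "day", "food_code", "amount_g"]
    )
    dataset = SurveyDataset(
        survey_id=config.survey_id,
        individuals=individuals,
        records=records,
        catalogue=FoodCatalogue(catalogue_df),
    ).validate()
    return dataset, composite_rules


# --------------------------------------------------------------------------
# Closed-form expectations for parameter-recovery tests


def expected_observed_consumer_rate(spec: FoodSpec, n_reporting_days: int) -> float:
    """Probability an individual shows any positive amount of the food:
    planted consumer probability times the chance of at least one consuming
    day."""
    detect = 1.0 - (1.0 - spec.day_probability) ** n_reporting_days
    return spec.consumer_probability * detect


def expected_consumers_only_mean(
    spec: FoodSpec, n_reporting_days: int, body_weight: float
) -> float:
    """Expected g/kg bw/day among observed consumers (fixed body weight).

    Per consuming day the amount is log-normal with mean
    exp(meanlog + sdlog^2/2); the individual mean divides the day sum by the
    number of reporting days, and conditioning on at least one consuming
    day rescales the expected number of consuming days."""
    m = math.exp(spec.meanlog + spec.sdlog**2 / 2.0)
    q, d = spec.day_probability, n_reporting_days
    detect = 1.0 - (1.0 - q) ** d
    if detect == 0:
        return 0.0
    expected_days = q * d / detect
    return expected_days * m / d / body_weight


# --------------------------------------------------------------------------
# Planted scenarios


@dataclass
class PlantedScenario:
    """A tiny survey/list pair with a machine-readable expected outcome."""

    kind: str
    surveys: list[SurveyDataset]
    food_list: FoodList | None
    run_config: RunConfig
    expected: dict
    composite_rules: list[CompositeRule] = dc_field(default_factory=list)


def _simple_survey(
    survey_id: str,
    groups: Sequence[tuple[str, float, float, int]],  # (label, lower, upper, n)
    catalogue_rows: Sequence[tuple[str, str, str, bool]],
    consumption: Sequence[tuple[str, str, float]],  # (individual_id, code, grams)
    body_weight: float = 10.0,
) -> SurveyDataset:
    """Deterministic one-day survey: unit weights, fixed body weight."""
    ind_rows = []
    for label, lower, upper, n in groups:
        for i in range(n):
            ind_rows.append(
                {
                    "id": f"{survey_id}-{label}-{i:04d}",
                    "survey_id": survey_id,
                    "age": (lower + upper) / 2.0,
                    "sex": "f" if i % 2 else "m",
                    "body_weight": body_weight,
                    "sampling_weight": 1.0,
                    "n_reporting_days": 1,
                    "breastfed": False,
                }
            )
    individuals = pd.DataFrame(ind_rows)
    catalogue = pd.DataFrame(
        list(catalogue_rows),
        columns=["food_code", "label", "main_group", "is_unspecified"],
    )
    records = pd.DataFrame(
        [
            {"individual_id": i, "day": 1, "food_code": c, "amount_g": g}
            for i, c, g in consumption
        ],
        columns=["individual_id", "day", "food_code", "amount_g"],
    )
    return SurveyDataset(
        survey_id=survey_id,
        individuals=individuals,
        records=records,
        catalogue=FoodCatalogue(catalogue),
    ).validate()


def _brute_force_min_cover(
    means: dict[str, float], total: float, threshold: float
) -> int | None:
    """Smallest subset cardinality reaching threshold x total, by exhaustive
    enumeration; None when no subset reaches it."""
    keys = list(means)
    target = threshold * total - 1e-12
    for k in range(0, len(keys) + 1):
        for combo in itertools.combinations(keys, k):
            if sum(means[c] for c in combo) >= target:
                return k
    return None


def generate_planted_scenario(kind: str, seed: int = 0) -> PlantedScenario:
    """Emit a small survey/list pair plus its independently computed outcome.

    Kinds: minimal_cover, deficient_cell, prunable_food, infeasible_cell,
    list_turnover.
    """
    rng = np.random.default_rng(seed)
    if kind == "minimal_cover":
        return _scenario_minimal_cover(rng)
    if kind == "deficient_cell":
        return _scenario_deficient_cell(rng)
    if kind == "prunable_food":
        return _scenario_prunable_food(rng)
    if kind == "infeasible_cell":
        return _scenario_infeasible_cell(rng)
    if kind == "list_turnover":
        return _scenario_list_turnover(rng)
    raise ValueError(f"unknown planted scenario kind {kind!r}")


_G = "Fruit and fruit products"
_AGE = ("a", 1.0, 3.0)


def _base_run_config(age_groups: Sequence[tuple[str, float, float]]) -> RunConfig:
    return RunConfig(
        age_groups=[AgeGroup(label=l, lower=lo, upper=hi) for l, lo, hi in age_groups]
    )


def _scenario_minimal_cover(rng: np.random.Generator) -> PlantedScenario:
    """Random single-cell candidate set; expectation = exhaustive minimum."""
    n_foods = int(rng.integers(4, 9))
    codes = [f"F.{i:02d}" for i in range(n_foods)]
    n_ind = 20
    catalogue = [(c, f"food {c}", _G, False) for c in codes]
    consumption = []
    # every individual consumes every food; per-food gram levels random
    levels = rng.uniform(5.0, 120.0, size=n_foods)
    for i in range(n_ind):
        for c, lv in zip(codes, levels):
            consumption.append((f"pl-a-{i:04d}", c, float(lv * rng.uniform(0.5, 1.5))))
    survey = _simple_survey("pl", [( "a", 1.0, 3.0, n_ind)], catalogue, consumption)

    # independent arithmetic: mean_all per code with unit weights, bw 10, 1 day
    sums: dict[str, float] = {c: 0.0 for c in codes}
    for i, c, g in consumption:
        sums[c] += g / 10.0  # one day, bw 10
    means = {c: s / n_ind for c, s in sums.items()}
    total = sum(means.values())
    k = _brute_force_min_cover(means, total, 0.9)
    return PlantedScenario(
        kind="minimal_cover",
        surveys=[survey],
        food_list=None,
        run_config=_base_run_config([("a", 1.0, 3.0)]),
        expected={
            "candidate_means": means,
            "total_mean": total,
            "threshold": 0.9,
            "min_cardinality": k,
        },
    )


def _per_capita(survey_n: int, mean_gkg: float, n_consumers: int) -> float:
    """Grams per consumer making the all-individuals mean equal mean_gkg
    (unit weights, bw 10, one day)."""
    return mean_gkg * 10.0 * survey_n / n_consumers


def _scenario_deficient_cell(rng: np.random.Generator) -> PlantedScenario:
    """List covers ~85% of one cell; one residual food closes the gap."""
    n = 100
    base_share = float(rng.uniform(0.82, 0.86))
    # the closer takes most of the residual, so it is always the top
    # candidate and alone lifts the cell past 0.9
    closer_share = (1.0 - base_share) * float(rng.uniform(0.6, 0.75))
    minor_share = 1.0 - base_share - closer_share
    catalogue = [
        ("A.1", "staple", _G, False),
        ("B.1", "closer", _G, False),
        ("C.1", "minor", _G, False),
    ]
    consumption = []
    for i in range(n):
        iid = f"pl-a-{i:04d}"
        consumption.append((iid, "A.1", _per_capita(n, base_share * 100, n)))
        consumption.append((iid, "B.1", _per_capita(n, closer_share * 100, n)))
        consumption.append((iid, "C.1", _per_capita(n, minor_share * 100, n)))
    survey = _simple_survey("pl", [("a", 1.0, 3.0, n)], catalogue, consumption)
    food_list = FoodList(
        version="old",
        foods=[
            TDSFood(
                id="staple", name="staple", main_group=_G,
                member_codes=frozenset(["A.1"]),
            )
        ],
    )
    return PlantedScenario(
        kind="deficient_cell",
        surveys=[survey],
        food_list=food_list,
        run_config=_base_run_config([("a", 1.0, 3.0)]),
        expected={
            "cell": ["pl", "a", _G],
            "initial_fraction": base_share,
            "must_add_code": "B.1",
            "final_fraction": base_share + closer_share,
        },
    )


def _scenario_prunable_food(rng: np.random.Generator) -> PlantedScenario:
    """Two age groups; F1 closes the first gap but becomes redundant (and
    has <5% consumers) once F2, needed for the second group, is added."""
    n = 100
    catalogue = [
        ("A.1", "staple", _G, False),
        ("F1.1", "niche", _G, False),
        ("F2.1", "popular", _G, False),
        ("D.1", "other", _G, False),
    ]
    # shares per age group cell (sum to 1 within each cell)
    a1 = {"A.1": 0.87, "F1.1": 0.05, "F2.1": 0.04, "D.1": 0.04}
    a2 = {"A.1": 0.85, "F1.1": 0.0, "F2.1": 0.10, "D.1": 0.05}
    # consumer counts; F1 has 2% consumers in a1 (and none in a2)
    consumers = {
        ("a1", "A.1"): n, ("a1", "F1.1"): 2, ("a1", "F2.1"): 50, ("a1", "D.1"): 60,
        ("a2", "A.1"): n, ("a2", "F1.1"): 0, ("a2", "F2.1"): 50, ("a2", "D.1"): 60,
    }
    consumption = []
    for grp, shares in (("a1", a1), ("a2", a2)):
        for code, share in shares.items():
            k = consumers[(grp, code)]
            if k == 0 or share == 0:
                continue
            per = _per_capita(n, share * 100, k)
            for i in range(k):
                consumption.append((f"pl-{grp}-{i:04d}", code, per))
    survey = _simple_survey(
        "pl", [("a1", 1.0, 3.0, n), ("a2", 3.0, 5.0, n)], catalogue, consumption
    )
    food_list = FoodList(
        version="old",
        foods=[
            TDSFood(
                id="staple", name="staple", main_group=_G,
                member_codes=frozenset(["A.1"]),
            )
        ],
    )
    return PlantedScenario(
        kind="prunable_food",
        surveys=[survey],
        food_list=food_list,
        run_config=_base_run_config([("a1", 1.0, 3.0), ("a2", 3.0, 5.0)]),
        expected={
            # F1 (largest residual in a1) is added first and lifts a1 to 0.92;
            # F2 is added for a2; F2's spill-over keeps a1 at 0.91 without F1,
            # and F1 has 2% consumers everywhere, so F1 must be pruned.
            "added_then_pruned_code": "F1.1",
            "final_added_codes": ["F2.1"],
            "final_fractions": {"a1": 0.91, "a2": 0.95},
        },
    )


def _scenario_infeasible_cell(rng: np.random.Generator) -> PlantedScenario:
    """Unspecified residual mass caps achievable coverage below threshold."""
    n = 50
    selectable = float(rng.uniform(3.0, 5.0))
    unspecified = float(rng.uniform(5.0, 7.0))
    catalogue = [
        ("N.1", "almonds", _G, False),
        ("N.NFS", "not further specified nuts", _G, True),
    ]
    consumption = []
    for i in range(n):
        iid = f"pl-a-{i:04d}"
        consumption.append((iid, "N.1", selectable * 10.0))
        consumption.append((iid, "N.NFS", unspecified * 10.0))
    survey = _simple_survey("pl", [("a", 1.0, 3.0, n)], catalogue, consumption)
    food_list = FoodList(
        version="old",
        foods=[
            TDSFood(
                id="almonds", name="almonds", main_group=_G,
                member_codes=frozenset(["N.1"]),
            )
        ],
    )
    max_fraction = selectable / (selectable + unspecified)
    return PlantedScenario(
        kind="infeasible_cell",
        surveys=[survey],
        food_list=food_list,
        run_config=_base_run_config([("a", 1.0, 3.0)]),
        expected={
            "cell": ["pl", "a", _G],
            "feasible": False,
            "max_fraction": max_fraction,
        },
    )


def _scenario_list_turnover(rng: np.random.Generator) -> PlantedScenario:
    """Old food B loses all consumers; new food C becomes indispensable."""
    n = 100
    catalogue = [
        ("A.1", "apples", _G, False),
        ("B.1", "quince", _G, False),
        ("C.1", "mango", _G, False),
        ("D.1", "medlar", _G, False),
    ]
    shares = {"A.1": 0.70, "C.1": 0.25, "D.1": 0.05}  # B.1 absent in new data
    consumption = []
    for code, share in shares.items():
        per = _per_capita(n, share * 100, n)
        for i in range(n):
            consumption.append((f"pl-a-{i:04d}", code, per))
    survey = _simple_survey("pl", [("a", 1.0, 3.0, n)], catalogue, consumption)
    old_list = FoodList(
        version="old",
        foods=[
            TDSFood(id="apples", name="apples", main_group=_G,
                    member_codes=frozenset(["A.1"])),
            TDSFood(id="quince", name="quince", main_group=_G,
                    member_codes=frozenset(["B.1"])),
        ],
    )
    # brute-force expectation: descending shares A (0.70) then C (0.25)
    # reach 0.95 >= 0.9; quince contributes nothing and is dropped.
    return PlantedScenario(
        kind="list_turnover",
        surveys=[survey],
        food_list=old_list,
        run_config=_base_run_config([("a", 1.0, 3.0)]),
        expected={
            "retained": ["apples"],
            "removed": ["quince"],
            "added_codes": ["C.1"],
        },
    )
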