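"""Domain model, validation and CSV/YAML input-output for TDS food-list pipelines.

A total diet study (TDS) samples a fixed list of aggregate *foods* meant to
cover at least 90% of the population's diet, measured in grams per kilogram
body weight per day.  The objects here describe the raw material of that
selection: a dietary survey (individuals plus day-level consumption records),
a hierarchical food catalogue partitioned into main food groups, and the food
list itself — named aggregates of catalogue codes, each belonging to exactly
one main group.

All tabular data are held as pandas DataFrames with fixed column schemas; the
classes wrap them with referential-integrity validation so downstream stages
can assume consistency.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "SchemaError",
    "IntegrityError",
    "ValidationError",
    "AgeGroup",
    "FoodCatalogue",
    "SurveyDataset",
    "TDSFood",
    "FoodList",
    "RunConfig",
    "read_catalogue",
    "read_survey",
    "write_survey",
    "read_food_list",
    "write_food_list",
    "read_config",
    "write_config",
]


class SchemaError(ValueError):
    """A CSV file does not conform to its declared column schema."""


class IntegrityError(ValueError):
    """A record references an entity (individual, food code) that does not exist."""


class ValidationError(ValueError):
    """A field value violates a domain invariant (e.g. non-positive body weight)."""


# --------------------------------------------------------------------------
# Column schemas (CSV dialect: comma-separated, UTF-8, header row, "." decimal)

INDIVIDUALS_COLUMNS = [
    "id",
    "survey_id",
    "age",
    "sex",
    "body_weight",
    "sampling_weight",
    "n_reporting_days",
    "breastfed",
]
RECORDS_COLUMNS = ["individual_id", "day", "food_code", "amount_g"]
CATALOGUE_COLUMNS = ["food_code", "label", "main_group", "is_unspecified"]
FOODLIST_COLUMNS = ["food_id", "name", "main_group", "member_codes", "origin"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _as_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].unique().tolist()
        raise SchemaError(f"cannot interpret boolean values {bad}")
    return out.astype(bool)


# --------------------------------------------------------------------------
# Age groups


class AgeGroup(BaseModel):
    """Half-open age interval [lower, upper) in years, e.g. '0.5-<1 y'."""

    model_config = {"frozen": True}

    label: str
    lower: float = Field(ge=0)
    upper: float

    @model_validator(mode="after")
    def _ordered(self) -> "AgeGroup":
        if not self.lower < self.upper:
            raise ValueError(f"age group {self.label!r}: lower must be < upper")
        return self

    def contains(self, age: float) -> bool:
        return self.lower <= age < self.upper


def check_age_groups_disjoint(groups: Sequence[AgeGroup]) -> None:
    ordered = sorted(groups, key=lambda g: g.lower)
    for a, b in zip(ordered, ordered[1:]):
        if b.lower < a.upper:
            raise ValidationError(
                f"age groups {a.label!r} and {b.label!r} overlap"
            )


def assign_age_group(ages: pd.Series, groups: Sequence[AgeGroup]) -> pd.Series:
    """Label each age with its group; ages outside every group get NA."""
    out = pd.Series(pd.NA, index=ages.index, dtype="object")
    for g in groups:
        out[(ages >= g.lower) & (ages < g.upper)] = g.label
    return out


# --------------------------------------------------------------------------
# Food catalogue


@dataclass(frozen=True)
class FoodCatalogue:
    """The food-code hierarchy: dotted codes, labels, 19-ish main groups.

    ``is_unspecified`` marks residual codes ("not further specified ...")
    that can never be a member of a TDS food and therefore always remain in
    the unmapped residual of a coverage audit.
    """

    table: pd.DataFrame  # columns: food_code, label, main_group, is_unspecified

    def __post_init__(self) -> None:
        _require_columns(self.table, CATALOGUE_COLUMNS, "catalogue")
        if self.table["food_code"].duplicated().any():
            dupes = self.table.loc[
                self.table["food_code"].duplicated(), "food_code"
            ].tolist()
            raise ValidationError(f"catalogue: duplicate food codes {dupes}")

    @property
    def codes(self) -> set[str]:
        return set(self.table["food_code"])

    @property
    def main_groups(self) -> set[str]:
        return set(self.table["main_group"])

    def main_group_of(self, code: str) -> str:
        row = self.table.loc[self.table["food_code"] == code]
        if row.empty:
            raise IntegrityError(f"unknown food code {code!r}")
        return row["main_group"].iloc[0]

    @property
    def unspecified_codes(self) -> set[str]:
        return set(self.table.loc[self.table["is_unspecified"], "food_code"])

    def code_to_group(self) -> pd.Series:
        return self.table.set_index("food_code")["main_group"]


def read_catalogue(path: str | Path) -> FoodCatalogue:
    df = pd.read_csv(path, dtype={"food_code": str, "label": str, "main_group": str})
    _require_columns(df, CATALOGUE_COLUMNS, f"catalogue {path}")
    df["is_unspecified"] = _as_bool(df["is_unspecified"])
    return FoodCatalogue(df[CATALOGUE_COLUMNS].copy())


# --------------------------------------------------------------------------
# Survey dataset


@dataclass
class SurveyDataset:
    """One dietary survey: individuals, day-level records, and its catalogue.

    individuals columns: id, survey_id, age, sex, body_weight,
    sampling_weight, n_reporting_days, breastfed.
    records columns: individual_id, day, food_code, amount_g.
    """

    survey_id: str
    individuals: pd.DataFrame
    records: pd.DataFrame
    catalogue: FoodCatalogue

    def validate(self) -> "SurveyDataset":
        _require_columns(self.individuals, INDIVIDUALS_COLUMNS, "individuals")
        _require_columns(self.records, RECORDS_COLUMNS, "records")
        ind = self.individuals
        if ind["id"].duplicated().any():
            raise ValidationError(
                f"duplicate individual ids: {ind.loc[ind['id'].duplicated(), 'id'].tolist()}"
            )
        bad_bw = ind["body_weight"].isna() | (ind["body_weight"] <= 0)
        if bad_bw.any():
            raise ValidationError(
                "body_weight must be > 0; offending individuals: "
                f"{ind.loc[bad_bw, 'id'].tolist()}"
            )
        bad_w = ind["sampling_weight"].isna() | (ind["sampling_weight"] <= 0)
        if bad_w.any():
            raise ValidationError(
                "sampling_weight must be > 0; offending individuals: "
                f"{ind.loc[bad_w, 'id'].tolist()}"
            )
        if (ind["n_reporting_days"] < 1).any():
            raise ValidationError("n_reporting_days must be >= 1")
        if (ind["age"] < 0).any():
            raise ValidationError("age must be >= 0")

        rec = self.records
        if (rec["amount_g"] < 0).any():
            rows = rec.index[rec["amount_g"] < 0].tolist()
            raise ValidationError(f"amount_g must be >= 0; offending rows {rows}")
        unknown_ind = ~rec["individual_id"].isin(ind["id"])
        if unknown_ind.any():
            raise IntegrityError(
                "records reference unknown individuals "
                f"{sorted(rec.loc[unknown_ind, 'individual_id'].unique())} "
                f"at rows {rec.index[unknown_ind].tolist()}"
            )
        unknown_code = ~rec["food_code"].isin(self.catalogue.table["food_code"])
        if unknown_code.any():
            raise IntegrityError(
                "records reference unknown food codes "
                f"{sorted(rec.loc[unknown_code, 'food_code'].unique())} "
                f"at rows {rec.index[unknown_code].tolist()}"
            )
        days = rec.merge(
            ind[["id", "n_reporting_days"]], left_on="individual_id", right_on="id"
        )
        bad_day = (days["day"] < 1) | (days["day"] > days["n_reporting_days"])
        if bad_day.any():
            raise ValidationError(
                f"record day out of [1, n_reporting_days] at rows "
                f"{rec.index[bad_day.to_numpy()].tolist()}"
            )
        return self

    def analysis_individuals(self, config: "RunConfig") -> pd.DataFrame:
        """Individuals entering statistics: breastfed excluded if configured,
        sampling weights forced to 1.0 when weighting is off."""
        ind = self.individuals
        if config.exclude_breastfed:
            ind = ind.loc[~ind["breastfed"]]
        ind = ind.copy()
        if not config.use_sampling_weights:
            ind["sampling_weight"] = 1.0
        return ind

    def equals(self, other: "SurveyDataset") -> bool:
        return (
            self.survey_id == other.survey_id
            and self.individuals.reset_index(drop=True).equals(
                other.individuals.reset_index(drop=True)
            )
            and self.records.reset_index(drop=True).equals(
                other.records.reset_index(drop=True)
            )
            and self.catalogue.table.reset_index(drop=True).equals(
                other.catalogue.table.reset_index(drop=True)
            )
        )


def read_survey(
    individuals_path: str | Path,
    records_path: str | Path,
    catalogue_path: str | Path,
) -> SurveyDataset:
    """Load and validate one survey from its three CSV files.

    Missing sampling weights (empty cells) default to 1.0, the convention for
    surveys distributed without calibration weights.
    """
    catalogue = read_catalogue(catalogue_path)
    ind = pd.read_csv(
        individuals_path,
        dtype={"id": str, "survey_id": str, "sex": str},
        float_precision="round_trip",
    )
    _require_columns(ind, INDIVIDUALS_COLUMNS, f"individuals {individuals_path}")
    ind["breastfed"] = _as_bool(ind["breastfed"])
    for col in ("age", "body_weight", "sampling_weight"):
        ind[col] = ind[col].astype(float)
    ind["sampling_weight"] = ind["sampling_weight"].fillna(1.0)
    ind["n_reporting_days"] = ind["n_reporting_days"].astype(int)
    rec = pd.read_csv(
        records_path,
        dtype={"individual_id": str, "food_code": str},
        float_precision="round_trip",
    )
    _require_columns(rec, RECORDS_COLUMNS, f"records {records_path}")
    rec["day"] = rec["day"].astype(int)
    rec["amount_g"] = rec["amount_g"].astype(float)
    survey_ids = ind["survey_id"].unique()
    if len(survey_ids) != 1:
        raise ValidationError(
            f"individuals file must contain exactly one survey_id, got {list(survey_ids)}"
        )
    ds = SurveyDataset(
        survey_id=str(survey_ids[0]),
        individuals=ind[INDIVIDUALS_COLUMNS].copy(),
        records=rec[RECORDS_COLUMNS].copy(),
        catalogue=catalogue,
    )
    return ds.validate()


def write_survey(dataset: SurveyDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write individuals.csv, records.csv and catalogue.csv under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "individuals": out / "individuals.csv",
        "records": out / "records.csv",
        "catalogue": out / "catalogue.csv",
    }
    # %.17g makes the float64 columns round-trip bit-exactly
    dataset.individuals.to_csv(paths["individuals"], index=False, float_format="%.17g")
    dataset.records.to_csv(paths["records"], index=False, float_format="%.17g")
    dataset.catalogue.table.to_csv(paths["catalogue"], index=False)
    return paths


# --------------------------------------------------------------------------
# TDS foods and food lists

#: Origin tags: how a food earned its place on the list.
ORIGIN_RISK = "risk_assessment"
ORIGIN_TREND = "trend"
ORIGIN_CARRIED_ADULT = "carried_over_adult"


def consumption_origin(survey_id: str, age_group: str) -> str:
    return f"consumption:{survey_id}:{age_group}"


@dataclass(frozen=True)
class TDSFood:
    """A named aggregate food: a set of catalogue codes within one main group."""

    id: str
    name: str
    main_group: str
    member_codes: frozenset[str]
    origin: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.member_codes:
            raise ValidationError(f"TDS food {self.id!r} has no member codes")

    def with_origin(self, *tags: str) -> "TDSFood":
        return replace(self, origin=self.origin | frozenset(tags))


@dataclass
class FoodList:
    """An ordered, versioned collection of TDS foods.

    Member codes partition: no catalogue code may belong to two foods.
    ``is_unspecified`` codes may not be members at all.
    """

    version: str
    foods: list[TDSFood] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check_partition()

    def _check_partition(self) -> None:
        seen_ids: set[str] = set()
        seen_codes: dict[str, str] = {}
        for f in self.foods:
            if f.id in seen_ids:
                raise ValidationError(f"duplicate food id {f.id!r}")
            seen_ids.add(f.id)
            for c in f.member_codes:
                if c in seen_codes:
                    raise ValidationError(
                        f"food code {c!r} claimed by both {seen_codes[c]!r} and {f.id!r}"
                    )
                seen_codes[c] = f.id

    def validate_against(self, catalogue: FoodCatalogue) -> "FoodList":
        code_group = catalogue.code_to_group()
        unspecified = catalogue.unspecified_codes
        for f in self.foods:
            if f.main_group not in catalogue.main_groups:
                raise ValidationError(
                    f"food {f.id!r}: undeclared main group {f.main_group!r}"
                )
            for c in f.member_codes:
                if c not in code_group.index:
                    raise IntegrityError(f"food {f.id!r}: unknown member code {c!r}")
                if c in unspecified:
                    raise ValidationError(
                        f"food {f.id!r}: member code {c!r} is an unspecified "
                        "residual code and may not be mapped"
                    )
                if code_group[c] != f.main_group:
                    raise ValidationError(
                        f"food {f.id!r} ({f.main_group}): member code {c!r} "
                        f"belongs to main group {code_group[c]!r}"
                    )
        return self

    def __len__(self) -> int:
        return len(self.foods)

    def __iter__(self):
        return iter(self.foods)

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.foods]

    def get(self, food_id: str) -> TDSFood:
        for f in self.foods:
            if f.id == food_id:
                return f
        raise KeyError(food_id)

    def code_to_food(self) -> dict[str, str]:
        """Mapping member catalogue code -> owning food id."""
        return {c: f.id for f in self.foods for c in f.member_codes}

    def food_main_groups(self) -> dict[str, str]:
        return {f.id: f.main_group for f in self.foods}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "food_id": [f.id for f in self.foods],
                "name": [f.name for f in self.foods],
                "main_group": [f.main_group for f in self.foods],
                "member_codes": ["|".join(sorted(f.member_codes)) for f in self.foods],
                "origin": ["|".join(sorted(f.origin)) for f in self.foods],
            }
        )


def read_food_list(
    path: str | Path,
    catalogue: FoodCatalogue | None = None,
    version: str | None = None,
) -> FoodList:
    df = pd.read_csv(path, dtype=str).fillna({"origin": ""})
    _require_columns(df, FOODLIST_COLUMNS, f"food list {path}")
    foods = []
    for row in df.itertuples(index=False):
        foods.append(
            TDSFood(
                id=row.food_id,
                name=row.name,
                main_group=row.main_group,
                member_codes=frozenset(
                    c for c in str(row.member_codes).split("|") if c
                ),
                origin=frozenset(t for t in str(row.origin).split("|") if t),
            )
        )
    fl = FoodList(version=version or Path(path).stem, foods=foods)
    if catalogue is not None:
        fl.validate_against(catalogue)
    return fl


def write_food_list(food_list: FoodList, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    food_list.to_frame().to_csv(path, index=False)
    return path


# --------------------------------------------------------------------------
# Run configuration


class RunConfig(BaseModel):
    """Parameters of one food-list build/update run.

    coverage_threshold
        Minimum fraction of mean consumption (g/kg bw/day) a list must cover
        per main food group and age group.  The TDS convention is 0.90.
    consumer_rate_cutoff
        Foods consumed by less than this (weighted) fraction of individuals
        in every age group are pruning candidates.  Convention: 0.05.
    pct_difference_denominator
        Which survey's mean sits in the denominator of relative consumption
        differences between an old and a new survey ("new" or "old").
    consumers_only_filter
        When true, the consumer-rate cutoff is applied as a hard filter on
        candidates before selection (the strict variant that sacrifices
        coverage for a shorter list).
    """

    coverage_threshold: float = Field(default=0.90, gt=0, le=1)
    consumer_rate_cutoff: float = Field(default=0.05, ge=0, lt=1)
    exclude_breastfed: bool = True
    use_sampling_weights: bool = True
    stratify_by_sex: bool = False
    age_groups: list[AgeGroup] = Field(default_factory=list)
    extra_foods: list[TDSFood] = Field(default_factory=list)
    pct_difference_denominator: str = "new"
    consumers_only_filter: bool = False
    seed: int = 0

    model_config = {"arbitrary_types_allowed": True}

    @field_validator("pct_difference_denominator")
    @classmethod
    def _denominator(cls, v: str) -> str:
        if v not in {"new", "old"}:
            raise ValueError("pct_difference_denominator must be 'new' or 'old'")
        return v

    @model_validator(mode="after")
    def _groups_disjoint(self) -> "RunConfig":
        if self.age_groups:
            check_age_groups_disjoint(self.age_groups)
        return self


def _food_to_dict(f: TDSFood) -> dict:
    return {
        "id": f.id,
        "name": f.name,
        "main_group": f.main_group,
        "member_codes": sorted(f.member_codes),
        "origin": sorted(f.origin),
    }


def _food_from_dict(d: Mapping) -> TDSFood:
    return TDSFood(
        id=d["id"],
        name=d.get("name", d["id"]),
        main_group=d["main_group"],
        member_codes=frozenset(d["member_codes"]),
        origin=frozenset(d.get("origin", [])),
    )


def read_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "age_groups" in raw:
        raw["age_groups"] = [AgeGroup(**g) for g in raw["age_groups"]]
    if "extra_foods" in raw:
        raw["extra_foods"] = [_food_from_dict(f) for f in raw["extra_foods"]]
    return RunConfig(**raw)


def write_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    data = config.model_dump(exclude={"age_groups", "extra_foods"})
    data["age_groups"] = [g.model_dump() for g in config.age_groups]
    data["extra_foods"] = [_food_to_dict(f) for f in config.extra_foods]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
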