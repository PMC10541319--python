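"""Shared fixtures: programmatically built miniature surveys and lists."""

from __future__ import annotations

import pandas as pd
import pytest

from tdslist import FoodCatalogue, FoodList, SurveyDataset, TDSFood

GROUP_FRUIT = "Fruit and fruit products"
GROUP_GRAIN = "Grains and grain-based products"


def make_catalogue(rows):
    """rows: (food_code, label, main_group, is_unspecified)"""
    return FoodCatalogue(
        pd.DataFrame(
            rows, columns=["food_code", "label", "main_group", "is_unspecified"]
        )
    )


def make_survey(
    individuals,
    records,
    catalogue,
    survey_id="s1",
    validate=True,
):
    """individuals: (id, age, body_weight, sampling_weight, n_days[, breastfed])
    records: (individual_id, day, food_code, amount_g)"""
    ind_rows = []
    for row in individuals:
        iid, age, bw, w, n_days = row[:5]
        breastfed = row[5] if len(row) > 5 else False
        ind_rows.append(
            {
                "id": iid,
                "survey_id": survey_id,
                "age": age,
                "sex": "f",
                "body_weight": bw,
                "sampling_weight": w,
                "n_reporting_days": n_days,
                "breastfed": breastfed,
            }
        )
    ds = SurveyDataset(
        survey_id=survey_id,
        individuals=pd.DataFrame(ind_rows),
        records=pd.DataFrame(
            records, columns=["individual_id", "day", "food_code", "amount_g"]
        ),
        catalogue=catalogue,
    )
    return ds.validate() if validate else ds


@pytest.fixture
def fruit_catalogue():
    return make_catalogue(
        [
            ("F.1", "apple", GROUP_FRUIT, False),
            ("F.2", "banana", GROUP_FRUIT, False),
            ("F.3", "mango", GROUP_FRUIT, False),
            ("F.NFS", "not further specified fruit", GROUP_FRUIT, True),
            ("G.1", "bread", GROUP_GRAIN, False),
            ("G.2", "pasta", GROUP_GRAIN, False),
        ]
    )


@pytest.fixture
def small_survey(fruit_catalogue):
    """Three individuals, two days, mixed consumption."""
    return make_survey(
        individuals=[
            ("i1", 2.0, 10.0, 1.0, 2),
            ("i2", 2.5, 12.0, 2.0, 2),
            ("i3", 4.0, 16.0, 1.0, 2),
        ],
        records=[
            ("i1", 1, "F.1", 30.0),
            ("i1", 2, "F.2", 10.0),
            ("i2", 1, "F.1", 60.0),
            ("i2", 1, "G.1", 50.0),
            ("i3", 2, "F.NFS", 20.0),
            ("i3", 1, "G.2", 40.0),
        ],
        catalogue=fruit_catalogue,
    )


@pytest.fixture
def fruit_list():
    return FoodList(
        version="v1",
        foods=[
            TDSFood(id="apple", name="apple", main_group=GROUP_FRUIT,
                    member_codes=frozenset(["F.1"])),
            TDSFood(id="banana", name="banana", main_group=GROUP_FRUIT,
                    member_codes=frozenset(["F.2"])),
            TDSFood(id="bread", name="bread", main_group=GROUP_GRAIN,
                    member_codes=frozenset(["G.1"])),
        ],
    )
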