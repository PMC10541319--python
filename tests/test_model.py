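"""Domain types, validation and CSV round-trips."""

import pandas as pd
import pytest

import tdslist as t
from tdslist.model import ValidationError

from conftest import GROUP_FRUIT, GROUP_GRAIN, make_catalogue, make_survey


class TestAgeGroups:
    def test_half_open_membership(self):
        g = t.AgeGroup(label="1-<3 y", lower=1.0, upper=3.0)
        assert g.contains(1.0) and g.contains(2.999)
        assert not g.contains(3.0) and not g.contains(0.999)

    def test_overlapping_groups_rejected(self):
        with pytest.raises(Exception, match="overlap"):
            t.RunConfig(
                age_groups=[
                    t.AgeGroup(label="a", lower=0.5, upper=2.0),
                    t.AgeGroup(label="b", lower=1.5, upper=3.0),
                ]
            )

    def test_inverted_bounds_rejected(self):
        with pytest.raises(Exception):
            t.AgeGroup(label="bad", lower=3.0, upper=1.0)


class TestSurveyValidation:
    def test_well_formed_fixture_loads(self, small_survey):
        assert len(small_survey.individuals) == 3
        assert len(small_survey.records) == 6

    @pytest.mark.parametrize(
        "mutation, error, match",
        [
            ("unknown_code", t.IntegrityError, "X.99"),
            ("unknown_individual", t.IntegrityError, "ghost"),
            ("nonpositive_weight", ValidationError, "body_weight"),
            ("negative_amount", ValidationError, "amount_g"),
        ],
    )
    def test_single_invariant_violations_named(
        self, fruit_catalogue, mutation, error, match
    ):
        individuals = [("i1", 2.0, 10.0, 1.0, 2)]
        records = [("i1", 1, "F.1", 30.0)]
        if mutation == "unknown_code":
            records = [("i1", 1, "X.99", 30.0)]
        elif mutation == "unknown_individual":
            records = [("ghost", 1, "F.1", 30.0)]
        elif mutation == "nonpositive_weight":
            individuals = [("i1", 2.0, 0.0, 1.0, 2)]
        elif mutation == "negative_amount":
            records = [("i1", 1, "F.1", -5.0)]
        with pytest.raises(error, match=match):
            make_survey(individuals, records, fruit_catalogue)

    def test_missing_column_names_column(self, tmp_path, fruit_catalogue):
        fruit_catalogue.table.to_csv(tmp_path / "catalogue.csv", index=False)
        pd.DataFrame({"id": ["i1"]}).to_csv(tmp_path / "individuals.csv", index=False)
        pd.DataFrame(
            columns=["individual_id", "day", "food_code", "amount_g"]
        ).to_csv(tmp_path / "records.csv", index=False)
        with pytest.raises(t.SchemaError, match="body_weight"):
            t.read_survey(
                tmp_path / "individuals.csv",
                tmp_path / "records.csv",
                tmp_path / "catalogue.csv",
            )


class TestSurveyRoundTrip:
    def test_write_read_identity(self, small_survey, tmp_path):
        paths = t.write_survey(small_survey, tmp_path)
        back = t.read_survey(
            paths["individuals"], paths["records"], paths["catalogue"]
        )
        assert back.equals(small_survey)

    def test_generated_survey_round_trips(self, tmp_path):
        cfg = t.default_generator_config(seed=7, n_individuals=12)
        ds, _ = t.generate_survey(cfg)
        paths = t.write_survey(ds, tmp_path)
        back = t.read_survey(
            paths["individuals"], paths["records"], paths["catalogue"]
        )
        assert back.equals(ds)


class TestFoodList:
    def test_round_trip(self, fruit_list, fruit_catalogue, tmp_path):
        p = t.write_food_list(fruit_list, tmp_path / "fl.csv")
        back = t.read_food_list(p, fruit_catalogue, version="v1")
        assert back.version == fruit_list.version
        assert [f.id for f in back] == [f.id for f in fruit_list]
        for a, b in zip(back, fruit_list):
            assert a == b

    def test_two_food_fixture_loads(self, fruit_catalogue, tmp_path):
        df = pd.DataFrame(
            {
                "food_id": ["apple", "bread"],
                "name": ["apple", "bread"],
                "main_group": [GROUP_FRUIT, GROUP_GRAIN],
                "member_codes": ["F.1", "G.1"],
                "origin": ["", ""],
            }
        )
        df.to_csv(tmp_path / "fl.csv", index=False)
        fl = t.read_food_list(tmp_path / "fl.csv", fruit_catalogue)
        assert len(fl) == 2

    def test_code_claimed_twice_rejected(self):
        with pytest.raises(ValidationError, match="claimed by both"):
            t.FoodList(
                version="v",
                foods=[
                    t.TDSFood(id="a", name="a", main_group=GROUP_FRUIT,
                              member_codes=frozenset(["F.1"])),
                    t.TDSFood(id="b", name="b", main_group=GROUP_FRUIT,
                              member_codes=frozenset(["F.1", "F.2"])),
                ],
            )

    def test_duplicate_food_id_rejected(self):
        with pytest.raises(ValidationError, match="duplicate food id"):
            t.FoodList(
                version="v",
                foods=[
                    t.TDSFood(id="a", name="a", main_group=GROUP_FRUIT,
                              member_codes=frozenset(["F.1"])),
                    t.TDSFood(id="a", name="a2", main_group=GROUP_FRUIT,
                              member_codes=frozenset(["F.2"])),
                ],
            )

    def test_unspecified_member_code_rejected(self, fruit_catalogue):
        fl = t.FoodList(
            version="v",
            foods=[
                t.TDSFood(id="fruit", name="fruit", main_group=GROUP_FRUIT,
                          member_codes=frozenset(["F.NFS"])),
            ],
        )
        with pytest.raises(ValidationError, match="unspecified"):
            fl.validate_against(fruit_catalogue)

    def test_wrong_main_group_rejected(self, fruit_catalogue):
        fl = t.FoodList(
            version="v",
            foods=[
                t.TDSFood(id="odd", name="odd", main_group=GROUP_FRUIT,
                          member_codes=frozenset(["G.1"])),
            ],
        )
        with pytest.raises(ValidationError, match="main group"):
            fl.validate_against(fruit_catalogue)


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = t.RunConfig(
            coverage_threshold=0.85,
            consumer_rate_cutoff=0.03,
            age_groups=[t.AgeGroup(label="a", lower=0.5, upper=3.0)],
            extra_foods=[
                t.TDSFood(id="sheep_liver", name="sheep liver",
                          main_group="Meat and meat products",
                          member_codes=frozenset(["M.9"]),
                          origin=frozenset(["risk_assessment"])),
            ],
            seed=11,
        )
        p = t.write_config(cfg, tmp_path / "cfg.yaml")
        back = t.read_config(p)
        assert back == cfg

    def test_threshold_bounds(self):
        with pytest.raises(Exception):
            t.RunConfig(coverage_threshold=0.0)
        with pytest.raises(Exception):
            t.RunConfig(consumer_rate_cutoff=1.0)

    def test_weights_disabled_forces_unit_weights(self, small_survey):
        cfg = t.RunConfig(use_sampling_weights=False)
        ind = small_survey.analysis_individuals(cfg)
        assert (ind["sampling_weight"] == 1.0).all()

    def test_breastfed_excluded(self, fruit_catalogue):
        ds = make_survey(
            [("i1", 0.6, 8.0, 1.0, 1, True), ("i2", 0.7, 8.0, 1.0, 1, False)],
            [("i2", 1, "F.1", 10.0)],
            fruit_catalogue,
        )
        ind = ds.analysis_individuals(t.RunConfig())
        assert list(ind["id"]) == ["i2"]
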