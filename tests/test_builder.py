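"""Greedy covering selection, coverage audits, update strategies, diffs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tdslist as t
from conftest import GROUP_FRUIT, make_catalogue, make_survey


def brute_force_min_cardinality(means, total, threshold):
    """Exhaustive oracle: smallest subset size reaching threshold*total."""
    keys = list(means)
    target = threshold * total - 1e-12
    for k in range(len(keys) + 1):
        for combo in itertools.combinations(keys, k):
            if sum(means[c] for c in combo) >= target:
                return k
    return None


class TestSelectMinCovering:
    def test_inclusive_boundary(self):
        res = t.select_min_covering({"A": 9.0, "B": 1.0}, threshold=0.9)
        assert res.selected == ("A",) and res.feasible

    def test_four_candidate_example_matches_subset_enumeration(self):
        means = {"A": 5.0, "B": 3.0, "C": 1.5, "D": 0.5}
        res = t.select_min_covering(means, threshold=0.9)
        assert set(res.selected) == {"A", "B", "C"}
        assert brute_force_min_cardinality(means, sum(means.values()), 0.9) == 3

    def test_unspecified_mass_causes_infeasibility(self):
        # selectable 4 of total 10: even everything reaches only 40%
        res = t.select_min_covering({"A": 4.0}, threshold=0.9, total_mean=10.0)
        assert res.selected == ("A",)
        assert not res.feasible
        assert res.fraction == pytest.approx(0.4)

    def test_empty_candidates_positive_total(self):
        res = t.select_min_covering({}, threshold=0.9, total_mean=5.0)
        assert res.selected == () and not res.feasible

    def test_zero_total_trivially_covered(self):
        res = t.select_min_covering({}, threshold=0.9, total_mean=0.0)
        assert res.feasible and res.fraction == 1.0

    def test_ties_broken_lexicographically(self):
        res = t.select_min_covering({"b": 5.0, "a": 5.0}, threshold=0.5)
        assert res.selected == ("a",)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_greedy_matches_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        means = {f"f{i:02d}": float(rng.uniform(0, 10)) for i in range(n)}
        unspec = float(rng.uniform(0, 2))
        total = sum(means.values()) + unspec
        threshold = float(rng.uniform(0.5, 1.0))
        res = t.select_min_covering(means, threshold, total_mean=total)
        k = brute_force_min_cardinality(means, total, threshold)
        if k is None:
            assert not res.feasible
        else:
            assert res.feasible
            assert len(res.selected) == k


def _single_cell_survey(shares, n=10, unspecified_codes=()):
    """One age group, one main group; per-food all-individuals mean
    proportional to `shares`."""
    catalogue = [
        (code, code, GROUP_FRUIT, code in unspecified_codes) for code in shares
    ]
    records = []
    for code, share in shares.items():
        for i in range(n):
            records.append((f"i{i:03d}", 1, code, share * 10.0))
    individuals = [(f"i{i:03d}", 2.0, 10.0, 1.0, 1) for i in range(n)]
    return make_survey(individuals, records, make_catalogue(catalogue))


def _list_of(codes_by_id):
    return t.FoodList(
        version="v",
        foods=[
            t.TDSFood(id=fid, name=fid, main_group=GROUP_FRUIT,
                      member_codes=frozenset(codes))
            for fid, codes in codes_by_id.items()
        ],
    )


CFG = t.RunConfig(age_groups=[t.AgeGroup(label="a", lower=1.0, upper=3.0)])


def _harmonized(survey):
    return t.HarmonizedSurvey.from_survey(survey)


class TestAuditCoverage:
    def test_complete_list_full_coverage(self):
        survey = _single_cell_survey({"A.1": 8.0, "B.1": 2.0})
        rep = t.audit_coverage(
            _list_of({"a": ["A.1"], "b": ["B.1"]}), _harmonized(survey), CFG
        )
        assert rep.cells["fraction"].iloc[0] == pytest.approx(1.0)
        assert rep.overall["s1"] == pytest.approx(1.0)

    def test_empty_list_zero_coverage(self):
        survey = _single_cell_survey({"A.1": 8.0, "B.1": 2.0})
        rep = t.audit_coverage(
            t.FoodList(version="e", foods=[]), _harmonized(survey), CFG
        )
        assert rep.cells["fraction"].iloc[0] == 0.0

    def test_partial_coverage_hand_computed(self):
        survey = _single_cell_survey({"A.1": 8.0, "B.1": 2.0})
        rep = t.audit_coverage(_list_of({"a": ["A.1"]}), _harmonized(survey), CFG)
        assert rep.cells["fraction"].iloc[0] == pytest.approx(0.8)

    def test_unspecified_mass_in_denominator_and_feasibility(self):
        survey = _single_cell_survey(
            {"A.1": 4.0, "N.NFS": 6.0}, unspecified_codes={"N.NFS"}
        )
        rep = t.audit_coverage(_list_of({"a": ["A.1"]}), _harmonized(survey), CFG)
        cell = rep.cells.iloc[0]
        assert cell["fraction"] == pytest.approx(0.4)
        assert cell["max_fraction"] == pytest.approx(0.4)
        assert not cell["feasible"]


class TestBuildInitialList:
    def test_single_cell_equals_select_min_covering(self):
        survey = _single_cell_survey({"A.1": 5.0, "B.1": 3.0, "C.1": 1.5, "D.1": 0.5})
        fl = t.build_initial_list([_harmonized(survey)], CFG)
        assert sorted(next(iter(f.member_codes)) for f in fl) == ["A.1", "B.1", "C.1"]

    def test_union_over_demographic_groups(self):
        # two age groups consuming disjoint foods -> list is their union
        catalogue = make_catalogue(
            [("A.1", "a", GROUP_FRUIT, False), ("B.1", "b", GROUP_FRUIT, False)]
        )
        survey = make_survey(
            [("i1", 1.5, 10.0, 1.0, 1), ("i2", 3.5, 10.0, 1.0, 1)],
            [("i1", 1, "A.1", 50.0), ("i2", 1, "B.1", 50.0)],
            catalogue,
        )
        cfg = t.RunConfig(
            age_groups=[
                t.AgeGroup(label="young", lower=1.0, upper=3.0),
                t.AgeGroup(label="old", lower=3.0, upper=5.0),
            ]
        )
        fl = t.build_initial_list([_harmonized(survey)], cfg)
        assert sorted(f.id for f in fl) == ["A.1", "B.1"]
        origins = {f.id: f.origin for f in fl}
        assert any("young" in tag for tag in origins["A.1"])
        assert any("old" in tag for tag in origins["B.1"])

    def test_extra_foods_always_present(self):
        survey = _single_cell_survey({"A.1": 10.0})
        extra = t.TDSFood(
            id="sheep_liver", name="sheep liver",
            main_group="Meat and meat products",
            member_codes=frozenset(["M.9"]),
            origin=frozenset(["risk_assessment"]),
        )
        cfg = CFG.model_copy(update={"extra_foods": [extra]})
        fl = t.build_initial_list([_harmonized(survey)], cfg)
        assert "sheep_liver" in fl.ids


class TestExtendList:
    def test_already_covered_is_identity(self):
        survey = _single_cell_survey({"A.1": 9.5, "B.1": 0.5})
        old = _list_of({"a": ["A.1"]})
        new, rep, diff = t.extend_list(old, [_harmonized(survey)], CFG)
        assert new.ids == old.ids
        assert diff.added == () and diff.removed == ()

    def test_one_residual_food_closes_gap(self):
        sc = t.generate_planted_scenario("deficient_cell", seed=0)
        hs = [_harmonized(s) for s in sc.surveys]
        new, rep, diff = t.extend_list(sc.food_list, hs, sc.run_config)
        added_codes = {c for fid in diff.added for c in new.get(fid).member_codes}
        assert added_codes == {sc.expected["must_add_code"]}
        assert rep.cells["fraction"].iloc[0] == pytest.approx(
            sc.expected["final_fraction"]
        )

    def test_low_consumer_addition_pruned(self):
        sc = t.generate_planted_scenario("prunable_food", seed=0)
        hs = [_harmonized(s) for s in sc.surveys]
        new, rep, diff = t.extend_list(sc.food_list, hs, sc.run_config)
        added_codes = sorted(
            c for fid in diff.added for c in new.get(fid).member_codes
        )
        assert added_codes == sc.expected["final_added_codes"]
        assert sc.expected["added_then_pruned_code"] not in added_codes

    def test_monotone_containment_and_cellwise_improvement(self):
        rng_seeds = [1, 2, 3]
        for seed in rng_seeds:
            sc = t.generate_planted_scenario("deficient_cell", seed=seed)
            hs = [_harmonized(s) for s in sc.surveys]
            before = t.audit_coverage(sc.food_list, hs, sc.run_config)
            new, after, _ = t.extend_list(sc.food_list, hs, sc.run_config)
            assert set(sc.food_list.ids) <= set(new.ids)
            merged = before.cells.merge(
                after.cells,
                on=["survey_id", "main_group", "age_group"],
                suffixes=("_before", "_after"),
            )
            assert (
                merged["fraction_after"] >= merged["fraction_before"] - 1e-12
            ).all()

    def test_original_foods_never_removed_even_at_low_rate(self):
        # original food with one consumer out of 10 (10% > 5%? no — make 2%):
        catalogue = make_catalogue(
            [("A.1", "a", GROUP_FRUIT, False), ("B.1", "b", GROUP_FRUIT, False)]
        )
        individuals = [(f"i{i:03d}", 2.0, 10.0, 1.0, 1) for i in range(50)]
        records = [("i000", 1, "A.1", 10.0)]  # rate 2%
        records += [(f"i{i:03d}", 1, "B.1", 100.0) for i in range(50)]
        survey = make_survey(individuals, records, catalogue)
        old = _list_of({"a": ["A.1"], "b": ["B.1"]})
        new, rep, diff = t.extend_list(old, [_harmonized(survey)], CFG)
        assert "a" in new.ids  # kept despite 2% consumer rate


class TestRebuildList:
    def test_structurally_identical_survey_keeps_list(self):
        survey = _single_cell_survey({"A.1": 8.0, "B.1": 1.5, "C.1": 0.5})
        old = t.build_initial_list([_harmonized(survey)], CFG, version="old")
        new, rep, diff = t.rebuild_list(old, [_harmonized(survey)], CFG)
        assert diff.added == () and diff.removed == ()

    def test_planted_turnover_recovered(self):
        sc = t.generate_planted_scenario("list_turnover", seed=0)
        hs = [_harmonized(s) for s in sc.surveys]
        new, rep, diff = t.rebuild_list(sc.food_list, hs, sc.run_config)
        assert list(diff.retained) == sc.expected["retained"]
        assert list(diff.removed) == sc.expected["removed"]
        added_codes = sorted(
            c for fid in diff.added for c in new.get(fid).member_codes
        )
        assert added_codes == sc.expected["added_codes"]

    def test_carried_over_foods_retained_without_consumption(self):
        survey = _single_cell_survey({"A.1": 10.0})
        old = _list_of({"a": ["A.1"], "legacy": ["B.9"]})
        carried = [old.get("legacy")]
        # B.9 absent from the new survey's catalogue-consumption entirely
        new, rep, diff = t.rebuild_list(
            old, [_harmonized(survey)], CFG, carried_over=carried
        )
        assert "legacy" in new.ids
        assert "legacy" not in diff.removed
        assert t.ORIGIN_CARRIED_ADULT in new.get("legacy").origin


class TestDiffLists:
    def test_identical_lists(self):
        fl = _list_of({"a": ["A.1"], "b": ["B.1"]})
        d = t.diff_lists(fl, fl)
        assert set(d.retained) == {"a", "b"}
        assert d.removed == () and d.added == ()

    def test_forced_example(self):
        old = _list_of({"a": ["A.1"], "b": ["B.1"]})
        new = _list_of({"b": ["B.1"], "c": ["C.1"]})
        d = t.diff_lists(old, new)
        assert d.retained == ("b",)
        assert d.removed == ("a",)
        assert d.added == ("c",)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_partition_identities(self, seed):
        rng = np.random.default_rng(seed)
        pool = [f"f{i:02d}" for i in range(20)]
        old_ids = [f for f in pool if rng.random() < 0.5]
        new_ids = [f for f in pool if rng.random() < 0.5]
        old = _list_of({fid: [f"{fid}.c"] for fid in old_ids})
        new = _list_of({fid: [f"{fid}.c"] for fid in new_ids})
        d = t.diff_lists(old, new)
        assert len(d.retained) + len(d.added) == len(new)
        assert len(d.retained) + len(d.removed) == len(old)
        assert not (set(d.retained) & set(d.removed))
        assert not (set(d.retained) & set(d.added))
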