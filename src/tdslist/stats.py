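"""Weighted consumption statistics and between-survey comparison.

All consumption is expressed as grams per kilogram body weight per day
(g/kg bw/day): for one individual, grams summed over all reporting days,
divided by the number of reporting days (days without consumption count in
the denominator) and by body weight.  Group-level statistics are weighted by
the survey's calibration (sampling) weights:

    mean_all        = sum(w_i x_i) / sum(w_i)          over all individuals
    mean_consumers  = sum(w_i x_i) / sum(w_i x_i > 0)  over consumers only
    consumer_rate   = sum(w_i [x_i > 0]) / sum(w_i)

An individual is a consumer of a food when their individual mean is strictly
positive.  All statistics are invariant to rescaling the weights by a
positive constant and reduce to their classical unweighted forms when all
weights are equal.

Between-survey differences use a weighted Mann-Whitney rank-sum test: ranks
are midranks of the pooled sample and each observation contributes its
weight times its rank to the statistic; the null distribution permutes group
labels over (value, weight) pairs, enumerated exhaustively when feasible and
by Monte Carlo otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import AgeGroup, RunConfig, SurveyDataset, assign_age_group

__all__ = [
    "round_half_away",
    "individual_mean",
    "per_individual_intake",
    "summarize_intake",
    "group_mean",
    "consumer_rate",
    "pct_difference",
    "weighted_mann_whitney",
    "compare_surveys",
]

#: Exhaustive label-permutation enumeration is used up to this many arrangements.
MAX_EXACT_PERMUTATIONS = 20_000


def round_half_away(x, decimals: int = 0):
    """Round half away from zero (the convention of printed report tables).

    numpy/python round half to even; consumption reports round 0.5 up in
    magnitude (24.8 -> 25, -29.5 -> -30).
    """
    x = np.asarray(x, dtype=float)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    if decimals <= 0:
        out = out.astype(int) if out.ndim else int(out)
    elif out.ndim == 0:
        out = float(out)
    return out


# --------------------------------------------------------------------------
# Individual-level intake


def individual_mean(
    records: pd.DataFrame, body_weight: float, n_reporting_days: int
) -> dict[str, float]:
    """Per-food g/kg bw/day for one individual.

    Grams are summed over all days and divided by the number of reporting
    days and body weight; days without consumption contribute zero grams but
    stay in the denominator.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    if n_reporting_days < 1:
        raise ValueError("n_reporting_days must be >= 1")
    if records.empty:
        return {}
    key = "tds_food_id" if "tds_food_id" in records.columns else "food_code"
    sums = records.groupby(key)["amount_g"].sum()
    return (sums / n_reporting_days / body_weight).to_dict()


def per_individual_intake(
    records: pd.DataFrame, individuals: pd.DataFrame, key: str
) -> pd.DataFrame:
    """Long table (individual_id, key, gkg_day) of individual means.

    Individuals with no record for a key are simply absent (implicit zero);
    group-level aggregation restores them through the full-group weight
    denominator.
    """
    if records.empty:
        return pd.DataFrame(columns=["individual_id", key, "gkg_day"])
    sums = records.groupby(["individual_id", key], as_index=False)["amount_g"].sum()
    merged = sums.merge(
        individuals[["id", "body_weight", "n_reporting_days"]],
        left_on="individual_id",
        right_on="id",
        how="inner",
    )
    merged["gkg_day"] = (
        merged["amount_g"] / merged["n_reporting_days"] / merged["body_weight"]
    )
    return merged[["individual_id", key, "gkg_day"]]


def summarize_intake(
    records: pd.DataFrame,
    individuals: pd.DataFrame,
    key: str,
    stratum_col: str = "stratum",
) -> pd.DataFrame:
    """Weighted summary per (stratum, key).

    ``individuals`` must carry ``stratum_col`` (e.g. an age-group label) and
    ``sampling_weight``.  Individuals with a null stratum are excluded.
    Returns columns: stratum, key, mean_all, mean_consumers, consumer_rate,
    n_consumers_weighted, n_consumers_unweighted.  Keys with no consumer in
    a stratum are omitted (their mean_all is zero by definition).
    """
    ind = individuals.dropna(subset=[stratum_col])
    denom = ind.groupby(stratum_col)["sampling_weight"].sum().rename("w_total")

    intake = per_individual_intake(records, ind, key)
    intake = intake.merge(
        ind[["id", stratum_col, "sampling_weight"]],
        left_on="individual_id",
        right_on="id",
    )
    intake = intake.loc[intake["gkg_day"] > 0]
    if intake.empty:
        return pd.DataFrame(
            columns=[
                stratum_col, key, "mean_all", "mean_consumers", "consumer_rate",
                "n_consumers_weighted", "n_consumers_unweighted",
            ]
        )
    intake["wx"] = intake["sampling_weight"] * intake["gkg_day"]
    agg = intake.groupby([stratum_col, key]).agg(
        wx_sum=("wx", "sum"),
        w_consumers=("sampling_weight", "sum"),
        n_consumers_unweighted=("individual_id", "nunique"),
    )
    agg = agg.join(denom, on=stratum_col).reset_index()
    agg["mean_all"] = agg["wx_sum"] / agg["w_total"]
    agg["mean_consumers"] = agg["wx_sum"] / agg["w_consumers"]
    agg["consumer_rate"] = agg["w_consumers"] / agg["w_total"]
    agg = agg.rename(columns={"w_consumers": "n_consumers_weighted"})
    return agg[
        [
            stratum_col, key, "mean_all", "mean_consumers", "consumer_rate",
            "n_consumers_weighted", "n_consumers_unweighted",
        ]
    ]


# --------------------------------------------------------------------------
# Scalar group statistics


def group_mean(
    values: Sequence[float],
    weights: Sequence[float] | None = None,
    consumers_only: bool = False,
) -> float:
    """Weighted mean over all individuals, or over consumers (x > 0) only.

    Returns NaN (the flagged missing value) for consumers_only with zero
    consumers.
    """
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("group_mean of an empty group")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    if consumers_only:
        mask = x > 0
        if not mask.any():
            return float("nan")
        x, w = x[mask], w[mask]
    return float(np.sum(w * x) / np.sum(w))


def consumer_rate(
    values: Sequence[float], weights: Sequence[float] | None = None
) -> float:
    """Weighted fraction of individuals with strictly positive consumption."""
    x = np.asarray(values, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if x.size == 0:
        raise ValueError("consumer rate of an empty group")
    if (w <= 0).any():
        raise ValueError("weights must be > 0")
    return float(np.sum(w[x > 0]) / np.sum(w))


def pct_difference(
    mean_old: float, mean_new: float, denominator: str = "new"
) -> int | None:
    """Signed integer percent difference between two survey means.

    Default convention: 100 * (new - old) / new, rounded half away from
    zero.  Returns None when the denominator mean is zero (undefined).
    """
    denom = mean_new if denominator == "new" else mean_old
    if denom == 0:
        return None
    return int(round_half_away(100.0 * (mean_new - mean_old) / denom))


# --------------------------------------------------------------------------
# Weighted Mann-Whitney rank-sum test


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float
    p_value: float
    exact: bool  # whether the null was enumerated exhaustively


def weighted_mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    wx: Sequence[float] | None = None,
    wy: Sequence[float] | None = None,
    n_perm: int = 9_999,
    seed: int = 0,
) -> MannWhitneyResult:
    """Two-sided weighted Mann-Whitney rank-sum test.

    The statistic is T = sum over the first sample of w_i * r_i, where r_i
    are midranks of the pooled values.  The null permutes group labels over
    the pooled (value, weight) pairs: exhaustively when the number of
    arrangements is at most ``MAX_EXACT_PERMUTATIONS``, else by ``n_perm``
    Monte-Carlo draws with the given seed.  The two-sided p-value is the
    null probability of |T - E[T]| at least as large as observed.  With all
    weights equal to one, T is the classical rank-sum statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    wx = np.ones_like(x) if wx is None else np.asarray(wx, dtype=float)
    wy = np.ones_like(y) if wy is None else np.asarray(wy, dtype=float)
    if (wx <= 0).any() or (wy <= 0).any():
        raise ValueError("weights must be > 0")

    pooled = np.concatenate([x, y])
    weights = np.concatenate([wx, wy])
    n_x, n_tot = x.size, pooled.size
    ranks = rankdata(pooled)  # midranks over ties
    contrib = weights * ranks
    t_obs = float(contrib[:n_x].sum())

    if np.all(pooled == pooled[0]):  # degenerate: every pooled value tied
        return MannWhitneyResult(t_obs, 1.0, True)

    # E[T] under random assignment of which n_x observations carry the x label
    expectation = n_x / n_tot * contrib.sum()
    dev_obs = abs(t_obs - expectation)
    eps = 1e-9 * max(1.0, abs(expectation))

    n_arrangements = math.comb(n_tot, n_x)
    if n_arrangements <= MAX_EXACT_PERMUTATIONS:
        stats = np.fromiter(
            (contrib[list(idx)].sum()
             for idx in itertools.combinations(range(n_tot), n_x)),
            dtype=float,
            count=n_arrangements,
        )
        p = float(np.mean(np.abs(stats - expectation) >= dev_obs - eps))
        return MannWhitneyResult(t_obs, p, True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_tot)[:n_x]
        t = contrib[perm].sum()
        if abs(t - expectation) >= dev_obs - eps:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MannWhitneyResult(t_obs, float(p), False)


# --------------------------------------------------------------------------
# Between-survey comparison (main-group level, consumers only)


def _group_level_records(survey: SurveyDataset, records: pd.DataFrame) -> pd.DataFrame:
    """Attach the main food group to each (possibly harmonised) record."""
    code_to_group = survey.catalogue.code_to_group()
    out = records.copy()
    out["main_group"] = out["food_code"].map(code_to_group)
    return out


def compare_surveys(
    old_survey: SurveyDataset,
    new_survey: SurveyDataset,
    config: RunConfig,
    old_records: pd.DataFrame | None = None,
    new_records: pd.DataFrame | None = None,
    n_perm: int = 9_999,
    include_total: bool = True,
) -> pd.DataFrame:
    """Main-group x age-group comparison of consumers-only means.

    Emits one row per (main_group, age_group) plus, optionally, a TOTAL row
    per age group (all food pooled), with the weighted Mann-Whitney p-value
    on the consumers-only individual means and the percent difference under
    the configured denominator convention.
    """
    rows = []
    sides = {}
    for tag, survey, records in (
        ("old", old_survey, old_records),
        ("new", new_survey, new_records),
    ):
        rec = survey.records if records is None else records
        rec = _group_level_records(survey, rec)
        ind = survey.analysis_individuals(config)
        ind = ind.copy()
        ind["stratum"] = assign_age_group(ind["age"], config.age_groups)
        intake = per_individual_intake(rec, ind, "main_group")
        if include_total:
            total = rec.groupby("individual_id", as_index=False)["amount_g"].sum()
            total["main_group"] = "TOTAL"
            total_intake = per_individual_intake(total, ind, "main_group")
            intake = pd.concat([intake, total_intake], ignore_index=True)
        intake = intake.merge(
            ind[["id", "stratum", "sampling_weight"]],
            left_on="individual_id",
            right_on="id",
        ).dropna(subset=["stratum"])
        sides[tag] = intake

    groups = sorted(
        set(sides["old"]["main_group"]) | set(sides["new"]["main_group"]),
        key=lambda g: (g == "TOTAL", g),
    )
    age_labels = [g.label for g in config.age_groups]
    rng_seed = config.seed
    for age_label in age_labels:
        for grp in groups:
            cell = {}
            for tag in ("old", "new"):
                sub = sides[tag]
                sub = sub.loc[
                    (sub["main_group"] == grp)
                    & (sub["stratum"] == age_label)
                    & (sub["gkg_day"] > 0)
                ]
                cell[tag] = sub
            mean_old = (
                group_mean(cell["old"]["gkg_day"], cell["old"]["sampling_weight"])
                if len(cell["old"])
                else float("nan")
            )
            mean_new = (
                group_mean(cell["new"]["gkg_day"], cell["new"]["sampling_weight"])
                if len(cell["new"])
                else float("nan")
            )
            if np.isnan(mean_old) or np.isnan(mean_new):
                pct = None
            else:
                pct = pct_difference(
                    mean_old, mean_new, config.pct_difference_denominator
                )
            if len(cell["old"]) and len(cell["new"]):
                mw = weighted_mann_whitney(
                    cell["old"]["gkg_day"].to_numpy(),
                    cell["new"]["gkg_day"].to_numpy(),
                    cell["old"]["sampling_weight"].to_numpy(),
                    cell["new"]["sampling_weight"].to_numpy(),
                    n_perm=n_perm,
                    seed=rng_seed,
                )
                p_value = mw.p_value
            else:
                p_value = float("nan")
            rows.append(
                {
                    "main_group": grp,
                    "age_group": age_label,
                    "mean_old": mean_old,
                    "mean_new": mean_new,
                    "n_old_weighted": float(cell["old"]["sampling_weight"].sum()),
                    "n_old_unweighted": int(len(cell["old"])),
                    "n_new_weighted": float(cell["new"]["sampling_weight"].sum()),
                    "n_new_unweighted": int(len(cell["new"])),
                    "pct_difference": pct,
                    "p_value": p_value,
                    "significant": bool(p_value < 0.05)
                    if not np.isnan(p_value)
                    else False,
                }
            )
    return pd.DataFrame(rows)
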