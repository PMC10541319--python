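# Methods

## Scope and units

`tdslist` operates on dietary surveys: individuals (age, sex, body weight,
calibration/sampling weight, number of reporting days) and day-level
consumption records coded on a catalogue partitioned into 19 main food
groups.  Every consumption statistic is expressed in grams per kilogram
body weight per day (g/kg bw/day): for an individual, grams are summed over
*all* reporting days — days without consumption count in the denominator —
then divided by the number of days and by body weight.  Group-level
statistics weight individuals by their sampling weights; with all weights
equal they reduce exactly to the unweighted forms, and all of them are
invariant to rescaling the weights by a positive constant.

Breastfed infants are excluded from the analysis population by default
(their milk intake is unobserved, so their diet cannot be totalled).
Surveys distributed without calibration weights are handled by setting all
weights to 1; the `use_sampling_weights` flag forces that behaviour
globally.

## Harmonisation

Raw records pass through three stages in a fixed order:

1. **Composite decomposition.** A rule maps one composite code to
   components with gram proportions that must sum to 1 (tolerance 1e-9).
   Each matching record is replaced by one record per component on the
   same individual and day, so grams per (individual, day) are conserved
   exactly.  Only one level is supported; a rule whose component is itself
   composite is rejected at load, since dish recipes are expected to be
   expressed directly in terms of primary foods.
2. **Reconstitution.** Records of concentrates are re-coded to the
   as-consumed form with grams scaled by a declared factor (e.g. instant
   tea powder ×50 → prepared beverage).  This is the only stage that
   intentionally changes gram totals, and it is applied exactly once.
3. **Mapping.** A record whose code is a member of a food on the list is
   assigned to that food; everything else — including "not further
   specified" (NFS) residual codes, which may never be list members —
   stays in an explicit residual.  Mapped plus residual grams equal input
   grams.

Composites are decomposed *before* reconstitution because a dish component
may itself need reconstitution.

## Coverage and the greedy selection

Coverage of a list in a (main food group × age group) cell is the weighted
all-individuals mean of consumption mapped to list foods divided by the
cell's total mean, **including** NFS consumption in the denominator.  That
denominator choice is what makes infeasible cells possible: when NFS mass
alone exceeds 1 − threshold (the nuts-type case), no selection can reach
the threshold, and the cell is reported with `feasible = False` at its
maximum achievable fraction.  Per-survey overall coverage is
Σ covered / Σ total over the survey's cells (consumption-weighted, not an
average of fractions).

Selection within a cell sorts candidates by descending mean (ties broken
lexicographically by key, for reproducibility) and takes the shortest
prefix whose cumulative mean reaches `threshold × total`.  Non-negativity
of means makes this prefix a minimum-cardinality covering subset, which
the test suite verifies against exhaustive subset enumeration.  Threshold
comparisons carry an absolute tolerance of 1e−12 to absorb summation
order; zero-mean candidates are never selected since they cannot raise
coverage.

## Update strategies

* **Strategy 1 (audit).** The existing list is applied unchanged to the
  new surveys; the output is the per-cell and overall coverage report.
* **Strategy 2 (extend).** For every cell below threshold, residual
  candidate foods are added in descending mean order until the cell
  reaches the threshold or exhausts its candidates.  Afterwards, *newly
  added* foods whose weighted consumer rate is below the cutoff (default
  5%) in **every** demographic group are removed greedily — ascending by
  their largest cell mean, recomputing feasibility after each removal —
  whenever every cell stays at ≥ threshold or, for infeasible cells, at
  its achievable maximum.  Foods of the original list are never removed,
  preserving the structure (and inter-study comparability) of the
  existing list.
* **Strategy 3 (rebuild).** A fresh list is compiled from the new surveys
  by the same per-cell greedy rule, using the old list's foods as the
  aggregation template plus one candidate food per uncovered non-NFS
  catalogue code; it is then merged with carry-over foods for population
  groups without new data (tagged `carried_over_adult`) and with
  configured extra foods (risk-assessment / trend additions, which are
  configuration inputs, not computed).  Consumer-rate pruning then applies
  to all consumption-selected foods — never to carry-overs or extras.
  The diff against the old list attributes each added food to the
  survey(s) whose coverage demanded it.

Design choices where the procedure is genuinely open, encoded as defaults:

* pruning order is ascending by the food's maximum cell mean
  (least-consumed first), with constraints re-checked after each removal;
* a food is prunable only if its rate is below the cutoff in *every*
  demographic group — a food with ≥5% consumers anywhere is considered
  relevant for that subgroup;
* the candidate aggregation for residual codes is one candidate food per
  code; coarser expert groupings can be supplied as a template list;
* the strict consumers-only variant (`consumers_only_filter`) applies the
  rate cutoff as a hard filter on candidates *before* selection, trading
  coverage for a shorter list; cells may then legitimately end far below
  the threshold and are reported as such.

## Weighted statistics and the rank-sum test

Consumer status means a strictly positive individual mean.  Consumer rates
and consumer counts are weighted by default (an unweighted mode exists).
Percent differences between an old and a new survey wave are
`100 × (new − old) / new`, rounded half away from zero — the denominator
convention is configurable (`pct_difference_denominator`), with the new
wave as default because that is the convention under which published
comparison tables of this kind are internally consistent.

The weighted Mann–Whitney test statistic is T = Σ wᵢ rᵢ over the first
sample, with rᵢ the midranks of the pooled values (weights enter the sum,
not the ranks).  The null permutes group labels over the pooled
(value, weight) pairs: exhaustive enumeration when C(n, n₁) ≤ 20 000,
otherwise Monte Carlo with `n_perm` draws and a caller-supplied seed (the
p-value then uses the standard (hits + 1)/(n_perm + 1) correction).  The
two-sided p-value is P(|T − E[T]| ≥ |t_obs − E[T]|) with the exact
E[T] = (n₁/N) Σ wᵢ rᵢ.  With unit weights and no ties this reproduces the
classical exact two-sided Mann–Whitney p-value to machine precision
(verified against an independent implementation); an all-tied pooled
sample returns p = 1.  Only this permutation construction is claimed — the
test's behaviour under other weighted-rank formulations is not.

## Rounding and reporting

Reports round integer percents half away from zero and print g/kg bw/day
means to one decimal (same rule).  Coverage below threshold becomes an
explicit boolean column.  Re-rendering identical inputs is byte-identical,
and every printed integer is re-derivable from the CSV floats.  Cells in a
published-style comparison whose printed rounded means are not
self-consistent with their printed percent difference (rounding of
unpublished underlying data) are outside what the renderer attempts to
reproduce.

## Synthetic surveys

The generator emulates the structure of national dietary record surveys —
not any country's actual consumption levels:

* individuals per age group with normal body weights (floored at 20% of
  the group mean), log-normal sampling weights, four reporting days by
  default ("three plus one" convention);
* zero-inflated, right-skewed amounts: consumer status ~
  Bernoulli(consumer_probability), day-level consumption ~
  Bernoulli(day_probability), positive amounts log-normal
  (meanlog, sdlog).  Consumer probabilities across foods follow a
  Beta(0.8, 3) — a few popular foods, many rare ones;
* default catalogue: 19 main groups × 5–30 foods (uniformly drawn), with
  one NFS code per group and composite-dish codes (0.6/0.4 two-component
  recipes) living in the composite-dishes group;
* configurable fractions of records rerouted to NFS codes and emitted as
  composites (matching decomposition rules are emitted alongside).

What it does *not* model: intra-week day structure, seasonal effects,
correlated food choices, under-reporting, breast-milk volumes, or real
consumption magnitudes.  Passing tests therefore demonstrate algorithmic
correctness under the stated generative assumptions, not calibration to
any real population.

Planted scenarios (`generate_planted_scenario`) construct tiny
deterministic surveys — unit weights, fixed 10 kg body weight, one
reporting day, so every mean is exact — whose expected outcome is computed
inside the generator by independent arithmetic (subset enumeration for
minimal covers, closed-form share sums for coverage fractions), never by
the pipeline under test.  Seeds jitter magnitudes within ranges that
preserve the planted inequalities.

## Problem sizes and numerical notes

The test suite uses surveys of 20–150 individuals and planted-scenario
sweeps of 50 seeds per kind; parameter-recovery checks use n = 2000
individuals with day probability 1 and fixed body weight so the planted
rate and consumers-only mean have closed-form targets (assertions at 3
standard errors).  The acceptance script uses ~150 individuals per age
group across four surveys, sizes at which the pipeline's behaviour —
coverage near but not identically 90%, a handful of deficient cells,
single-digit extension counts — is stable across seeds while each full run
completes in seconds.  Exhaustive permutation enumeration in the rank-sum
test is capped at 20 000 arrangements; beyond that, Monte Carlo with 9 999
permutations by default.  All randomness flows through
`numpy.random.default_rng` seeded from configuration.

## Known limitations

* Expert-driven aggregation of similar low-consumer foods ("removed or
  further aggregated") is not automated; only removal is. Aggregations are
  supplied as template/list edits.
* Only a one-level main-group hierarchy plus arbitrary-depth codes is
  modelled; no full food-classification ontology.
* No usual-intake modelling (within/between-person variance), no nutrient
  or occurrence data, no exposure assessment: the package ends at the food
  list and its coverage audit.
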