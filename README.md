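# tdslist

Compilation, auditing and updating of **total diet study (TDS) food lists**
from dietary survey data.

A TDS measures chemical substances in foods prepared as consumed, pooled
into a fixed list of aggregate foods.  The list is the core of the study:
it must cover at least **90% of mean food consumption** — in grams per
kilogram body weight per day (g/kg bw/day) — within every main food group
and every age group of the target population.  When a new consumption
survey arrives years after the list was compiled, the study team must
decide whether the old list still covers the new diet and, if not, how to
update it.  `tdslist` implements that workflow end to end for
epidemiologists and exposure assessors:

* **harmonisation** of raw dietary records: composite dishes are broken
  into their components by gram proportions, concentrates are rescaled to
  their "as consumed" form, and records are mapped onto the aggregate
  foods of a list, with unmappable "not further specified" codes kept in an
  explicit residual;
* **weighted consumption statistics**: all-individuals and consumers-only
  means, weighted consumer rates, percent differences between survey
  waves, and a weighted Mann–Whitney rank-sum test with a
  label-permutation null;
* **list building and updating**: greedy minimal covering selection per
  (main food group × age group) cell, and three update strategies —
  audit the existing list unchanged (strategy 1), extend it where coverage
  falls short and prune low-consumer-rate additions (strategy 2), or
  rebuild it from scratch with carry-over for population groups without
  new data (strategy 3) — plus retained/removed/added list diffs;
* a **synthetic survey generator** with planted, recoverable structure,
  since the underlying national survey microdata are not redistributable.

## The selection rule

Within each main food group *g* and age group *a*, foods are sorted by
descending all-individuals mean consumption
x̄<sub>f</sub> = Σᵢ wᵢ xᵢf / Σᵢ wᵢ (sampling weights wᵢ; xᵢf the individual's
grams summed over reporting days, divided by the number of days and body
weight).  The shortest prefix with

&nbsp;&nbsp;&nbsp;&nbsp;Σ<sub>f∈prefix</sub> x̄<sub>f</sub> ≥ 0.9 · T<sub>g,a</sub>

is selected, where T<sub>g,a</sub> is the cell's total mean *including*
consumption on unmappable residual codes.  Because means are non-negative,
this greedy prefix is a minimum-cardinality covering subset.  A cell whose
residual mass alone exceeds 10% is *infeasible*: all selectable foods are
taken and the cell is reported at its maximum achievable fraction.
Low-consumer-rate pruning removes foods with a weighted consumer rate
below 5% in every age group, least-consumed first, only while every cell
stays at ≥90% (or at its infeasible maximum).

## Worked example

```python
import tdslist as t

# an older children's survey and a newly collected wave of the same population
old_cfg = t.default_generator_config(seed=1, n_individuals=150, survey_id="wave1")
new_cfg = old_cfg.model_copy(update={"seed": 8, "survey_id": "wave2"})
old, old_rules = t.generate_survey(old_cfg)
new, new_rules = t.generate_survey(new_cfg)

cfg = t.RunConfig(age_groups=old_cfg.age_group_labels(), seed=1)
h_old = t.HarmonizedSurvey.from_survey(old, old_rules)
h_new = t.HarmonizedSurvey.from_survey(new, new_rules)

foodlist = t.build_initial_list([h_old], cfg, version="2016")
audit = t.audit_coverage(foodlist, [h_new], cfg)          # strategy 1
extended, report, diff = t.extend_list(foodlist, [h_new], cfg)  # strategy 2

print(f"initial list: {len(foodlist)} foods")
print(f"coverage of the new survey: {100 * audit.overall['wave2']:.1f}%")
print(f"deficient cells before extension: {len(audit.deficient_cells())}")
print(f"extended list: {len(extended)} foods (+{len(diff.added)})")
```

prints

```
initial list: 217 foods
coverage of the new survey: 93.0%
deficient cells before extension: 4
extended list: 222 foods (+5)
```

The initial list compiled from wave 1 still covers 93.0% of wave 2's diet
overall, but 4 (main food group × age group) cells fall below 90%;
strategy 2 restores every feasible cell to ≥90% by adding 5 foods (after
pruning additions with <5% consumers wherever coverage allows).

A thin CLI wraps the same functions: `tds simulate`, `tds update
--approach {1,2,3}`, `tds report`.

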