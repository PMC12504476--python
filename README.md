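# pmcindex

A toolkit for **Policy Modeling Consistency (PMC) index** evaluation of
policy texts, built around the quantitative assessment of China's smart
older-adults-care (smart elder-care) policies. It is aimed at policy
analysts who score policy documents against a binary indicator system and
want the downstream numbers — indices, grades, rankings, improvement
paths, surface and radar diagrams, keyword co-occurrence networks —
computed reproducibly instead of in a spreadsheet.

## The model

An evaluation schema defines primary variables `X_1 … X_P` (policy
dimensions such as *Policy Nature*, *Policy Timeliness*, *Policy Tool*),
each holding `n_i` equally weighted binary secondary variables
`X_{ij} ∈ {0, 1}` (1 when the policy text satisfies the criterion). Then

```
X_i  = (1 / n_i) · Σ_j X_{ij}          primary score, X_i ∈ [0, 1]
PMC  = Σ_i X_i                          PMC index, PMC ∈ [0, P]
```

With the bundled schema (`P = 9`, 33 criteria, secondary counts
3,3,3,3,5,4,3,5,4) the index is graded as *Weak applicability*
(PMC ≤ 6.50), *Focused* (6.50 < PMC ≤ 7.50) or *Reasonable and Complete*
(PMC > 7.50).

Two conventions matter and are explicit in the API:

- **`rounded2` mode (default):** each `X_i` is rounded half-up to 2
  decimals *before* summation. This is the convention that reproduces
  published score tables — with plain fractional sums three of the ten
  bundled policies come out 0.01 lower.
- **Improvement paths:** the dimensions of a policy scoring strictly below
  the cross-policy mean, ordered by gap (mean − score) descending, ties
  broken by ascending dimension index.

The nine scores arranged row-major into a 3×3 matrix give the PMC
surface; its depressions (`1 − X_i`) localise a policy's weaknesses. A
separate text-mining stage builds weighted keyword co-occurrence networks
from a tokenised corpus (terms co-occur when they share a sentence/unit).

## Worked example

```python
from pmcindex import builtin_score_table, evaluate_all, group_mean, variable_means

table = builtin_score_table()           # 10 policies x 33 bits + metadata
results = evaluate_all(table)           # rounded2 mode, default grade scale
for r in sorted(results, key=lambda r: r.rank)[:3]:
    print(r.policy, r.pmc_index, r.grade)
print("mean:", group_mean(results, table.policies))
```

prints

```
P1 8.67 Reasonable and Complete
P6 8.47 Reasonable and Complete
P9 7.94 Reasonable and Complete
mean: 7.38
```

i.e. the national-level plan P1 scores highest (8.67 of 9: only its
*Policy Timeliness* dimension is imperfect), three of the ten policies
reach the top grade, and the cohort mean 7.38 sits in the *Focused* band.
`variable_means(results)` gives the per-dimension means
(0.77, 1.00, 0.50, …) showing *Policy Timeliness* (X3, mean 0.50) is the
weakest dimension across the cohort, and
`improvement_path(result, means)` orders each policy's below-mean
dimensions, e.g. `X3 → X1 → X9 → X8` for P3.

The `examples/` directory holds one short script per capability:
evaluation and ranking, surface/radar rendering with concavity reports,
co-occurrence network mining, and seeded synthetic-data generation.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged binary score table alone, the cohort's mean
PMC index, the individual indices of six representative policies, and the
count of top-grade policies, writing them as JSON. Everything is
recomputed at run time by the same code paths the library exposes.
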