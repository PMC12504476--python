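"""Evaluate the bundled 10 smart older-adults-care policies.

Loads the packaged 9x33 indicator schema and the 10-policy binary score
table, computes each policy's PMC index (primary scores rounded half-up to
2 decimals before summation), grades it, and prints the ranking plus the
cross-policy means the improvement analysis builds on.
"""

from pmcindex import (
    builtin_score_table,
    evaluate_all,
    group_mean,
    improvement_path,
    variable_means,
)

table = builtin_score_table()
results = evaluate_all(table)

print("policy  index  rank  grade")
for r in sorted(results, key=lambda r: r.rank):
    print(f"{r.policy:<6}  {r.pmc_index:5.2f}  {r.rank:>4}  {r.grade}")

means = variable_means(results)
print("\nper-dimension means (X1..X9):", " ".join(f"{m:.2f}" for m in means))
print("mean PMC index:", group_mean(results, table.policies))
print("provincial mean:", group_mean(results, ["P3", "P4", "P5", "P6"]))
print("municipal mean:", group_mean(results, ["P7", "P8", "P9", "P10"]))

# An index of 9 means every criterion is met; a dimension below the
# cross-policy mean joins that policy's improvement path, biggest gap first.
for r in sorted(results, key=lambda r: r.rank):
    path = improvement_path(r, means)
    arrows = " -> ".join(f"X{i}" for i in path) or "(none)"
    print(f"improvement path {r.policy}: {arrows}")
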