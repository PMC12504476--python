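# Methods

## Model and procedure

The toolkit evaluates a set of policies against a schema of `P` primary
variables, each aggregating `n_i` equally weighted binary criteria. A
policy's primary score is the mean of its bits, `X_i = Σ_j X_{ij} / n_i`,
and its PMC index is `Σ_i X_i ∈ [0, P]`. Grades partition the index range
with left-open/right-closed intervals; with the default scale the
boundaries 6.50 and 7.50 belong to the lower grade. The improvement path
of a policy lists the primaries scoring strictly below the cross-policy
mean, ordered by gap descending.

The model assumes (a) criteria are judged 0/1 by a human coder — the
package records and validates scores, it never scores raw text; (b) equal
weights within a primary, by construction (no weight field exists); and
(c) that comparing policies is meaningful only under one shared schema
and score mode.

## Rounding: the load-bearing convention

Published PMC score tables report each primary score to 2 decimals and an
index that equals the sum of those *reported* scores. The package
therefore defaults to `rounded2` mode: every primary score is rounded
half-up (2/3 → 0.67; Python's banker's rounding would be wrong here) to 2
decimals before summation, and all downstream quantities — grading,
ranking, group means, improvement-path gaps — consume the rounded values.
For the bundled cohort, fractional summation instead shifts P2
(7.49 → 7.48), P7 (6.91 → 6.90) and P9 (7.94 → 7.93); P2's printed grade
(*Focused*, requiring > 6.50 and ≤ 7.50) is insensitive to this, but the
0.01 differences make the convention observable and tested. `exact` mode
keeps primary scores as exact fractions (only the final report is
rounded) for principled re-analysis.

All internal arithmetic on reported values uses `decimal.Decimal`, so a
sum of 2-decimal scores is exact and no float fuzz can move a value
across a grade boundary. Improvement-path ties (equal gaps at 2 decimals)
break by ascending primary index — a deterministic, documented rule;
published orderings of tied dimensions are not consistent enough to infer
any other rule.

Ranking ties (equal indices) resolve stably by input order; the bundled
cohort has none.

## Bundled data

The package ships the smart older-adults-care indicator system (9
primaries / 33 criteria, labels and criterion texts included) and the
binary scoring of 10 representative Chinese policies (2 central, 4
provincial, 4 municipal, 2019–2024) with per-policy metadata (name,
issuing organ, release date, administrative level). Metadata never enters
the index computation; it only drives group means (e.g. provincial 7.28
vs municipal 7.12).

Score tables round-trip through three dialects: `long` (tidy
policy/secondary/value CSV, the canonical storage form), `wide` (one row
per policy, 33 bit columns) and `compact` (one row per primary, one
bitstring per policy — the layout the source table is printed in, kept
for fidelity). Validation enumerates every violation (non-binary cells,
missing cells, unknown ids, wrong-length bitstrings) rather than stopping
at the first.

## Surface, radar, concavity

The nine scores fill a 3×3 matrix row-major (row 1 = X1..X3). Rendering
upsamples the grid with bilinear interpolation onto a `(2f+1)²` grid
(default `f = 10`); bilinear values are bounded by the cell extremes, a
property the tests pin. Bicubic (order-3 spline) is available for
smoother figures but may overshoot slightly. The z-axis and colormap are
fixed to [0, 1] so surfaces are comparable across policies. Published
discussion of surface "concavity" is visual only; the package quantifies
it as `depression(X_i) = 1 − X_i` (an extension, clearly labelled as
such), so total depression equals `9 − PMC`.

Renders are deterministic: the Agg backend is forced, and volatile file
metadata (creation dates) is stripped, so identical inputs produce
byte-identical files.

## Text mining

A corpus is a list of documents split into co-occurrence units (default:
one sentence/line, split on newlines and CJK/Latin sentence enders). Term
frequencies count tokens after stopword removal; the network keeps the
`top_n` most frequent terms (frequency ties break lexicographically) with
edges weighting the number of units where both terms occur — or, with the
optional `window=k`, where they occur within `k` consecutive tokens.
Centrality is reported as weighted degree; nearness to the visual centre
of a drawn network is a layout artefact, not a statistic. Tokenization is
pluggable (whitespace default): segmentation quality for Chinese text is
explicitly out of scope and should be handled upstream.

## Synthetic data

`generate_score_table` draws each bit as an independent Bernoulli with a
per-criterion probability; the default probabilities are the empirical
per-criterion frequencies of the bundled table, so a simulated cohort has
the observed marginal scoring pattern. What the generator does **not**
emulate is the dependence between criteria visible in real scorings
(e.g. some criteria are satisfied by every policy); no published
generative model specifies it, so a green test on synthetic tables
establishes correctness of the pipeline, not realism of joint structure.
Whether the always-satisfied criteria are forced by the schema or merely
empirical is unstated, so the generator treats every probability as a
free parameter.

`generate_corpus` plants hub terms into every unit plus uniform filler
draws, which guarantees each hub's weighted degree is maximal — a known
structure for testing the network stage. Defaults (10 documents, 20 units
each, 5 fillers per unit) give stable hub dominance at toy scale.

All randomness flows through numpy's `default_rng` (PCG64), the single
named RNG; a seed fully determines every synthetic artifact across
platforms.

## Numerical and design choices

- Half-up rounding everywhere a value is reported (`_rounding.round_half_up`).
- Grade classification consumes the 2-decimal reported index.
- `upsample(factor=1)` is the identity; factors below 1 are rejected.
- Degenerate inputs: empty score tables evaluate to an error; empty
  corpora yield empty statistics; an empty policy list serialises to a
  header-only document in every dialect.
- Pipeline runs (`run_evaluation`) are atomic — all outputs are computed
  before the first byte is written — and idempotent on tabular outputs.

## Limitations

- The toolkit does not score policy texts against criteria; coder
  judgment (and its subjectivity) sits outside the package.
- Equal weighting is mandated by the model; no alternative weighting is
  offered.
- The concavity number and the co-occurrence network are re-implementations
  in spirit, not replications of any specific legacy tool's output.
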