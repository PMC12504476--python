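"""Policy Modeling Consistency (PMC) index computation.

For each policy, every primary variable scores the mean of its binary
criteria; the PMC index is the sum of the primary scores, ranging from 0 to
the number of primaries (9 for the bundled schema). Grades partition the
index range; the improvement path of a policy orders its below-average
dimensions by their gap to the cross-policy mean, largest first.

Two score modes exist:

``rounded2`` (default)
    Each primary score is rounded half-up to 2 decimals *before* summation.
    This is the convention that reproduces published score tables: rounding
    after summation instead can shift the reported index by 0.01.
``exact``
    Primary scores are kept as exact fractions; only the final reported
    index is rounded to 2 decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from fractions import Fraction
from typing import Iterable, Literal, Sequence

from ._rounding import round_half_up, to_decimal
from .errors import PmcError
from .scores import ScoreTable

__all__ = [
    "ScoreMode",
    "PrimaryScoreVector",
    "GradeScale",
    "PmcResult",
    "primary_scores",
    "pmc_index",
    "classify",
    "evaluate_all",
    "variable_means",
    "group_mean",
    "improvement_path",
]

ScoreMode = Literal["rounded2", "exact"]


@dataclass(frozen=True)
class PrimaryScoreVector:
    """Per-primary scores of one policy.

    The exact fractional scores are always retained; :attr:`scores` exposes
    the mode's reported view (2-decimal floats in ``rounded2``, full-precision
    floats in ``exact``).
    """

    policy: str
    fractions: tuple[Fraction, ...]
    mode: ScoreMode = "rounded2"

    def __post_init__(self) -> None:
        if any(f < 0 or f > 1 for f in self.fractions):
            raise PmcError("primary scores must lie in [0, 1]")

    @property
    def scores(self) -> tuple[float, ...]:
        if self.mode == "rounded2":
            return tuple(round_half_up(f) for f in self.fractions)
        return tuple(float(f) for f in self.fractions)

    def _decimals(self) -> tuple[Decimal, ...]:
        """Exact decimal view of the mode's scores (no float fuzz)."""
        if self.mode == "rounded2":
            return tuple(Decimal(f"{round_half_up(f):.2f}") for f in self.fractions)
        return tuple(to_decimal(f) for f in self.fractions)

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class GradeScale:
    """Left-open / right-closed grade intervals over the index range.

    The default scale: index <= 6.50 is "Weak applicability",
    6.50 < index <= 7.50 is "Focused", above 7.50 is
    "Reasonable and Complete". Classification is applied to the 2-decimal
    reported index.
    """

    breakpoints: tuple[float, ...] = (6.50, 7.50)
    labels: tuple[str, ...] = (
        "Weak applicability",
        "Focused",
        "Reasonable and Complete",
    )

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breakpoints) + 1:
            raise PmcError("need exactly one more label than breakpoints")
        if any(a >= b for a, b in zip(self.breakpoints, self.breakpoints[1:])):
            raise PmcError("breakpoints must be strictly increasing")


@dataclass(frozen=True)
class PmcResult:
    """Evaluation outcome for one policy."""

    policy: str
    primary_scores: PrimaryScoreVector
    pmc_index: float
    grade: str
    rank: int = field(default=0)


# ---------------------------------------------------------------------------
# operations


def primary_scores(
    table: ScoreTable, policy: str, mode: ScoreMode = "rounded2"
) -> PrimaryScoreVector:
    """Score every primary variable of *policy* as the mean of its bits."""
    if policy not in table.values.index:
        raise KeyError(f"unknown policy {policy!r}")
    fracs = []
    for primary in table.schema.primaries:
        bits = table.bits(policy, primary.index)
        fracs.append(Fraction(sum(bits), len(bits)))
    return PrimaryScoreVector(policy=policy, fractions=tuple(fracs), mode=mode)


def pmc_index(vector: PrimaryScoreVector) -> float:
    """Sum of the primary scores, reported to 2 decimals.

    In ``rounded2`` mode the summands are the already-rounded scores, so
    the sum is exact at 2 decimals; in ``exact`` mode the fractional sum
    is rounded only here.
    """
    return round_half_up(sum(vector._decimals(), Decimal(0)))


def classify(pmc: float, scale: GradeScale = GradeScale()) -> str:
    """Grade a reported PMC index on *scale* (right-closed intervals).

    The upper bound (number of primaries) is enforced by
    :func:`evaluate_all`, which knows the schema; here only non-negativity
    can be checked.
    """
    if pmc < 0:
        raise PmcError(f"PMC index {pmc} below 0")
    value = Decimal(f"{round_half_up(pmc):.2f}")
    position = sum(value > Decimal(repr(b)) for b in scale.breakpoints)
    return scale.labels[position]


def evaluate_all(
    table: ScoreTable,
    mode: ScoreMode = "rounded2",
    scale: GradeScale = GradeScale(),
) -> list[PmcResult]:
    """Evaluate every policy: scores, index, grade, and descending-index rank.

    Results are returned in the table's policy order; ranks are assigned by
    descending index with ties resolved stably by input order.
    """
    if table.n_policies == 0:
        raise PmcError("score table has no policies")
    n_primaries = table.schema.n_primaries
    partial = []
    for policy in table.policies:
        vector = primary_scores(table, policy, mode)
        index = pmc_index(vector)
        if index > n_primaries:
            raise PmcError(f"index {index} exceeds primary count {n_primaries}")
        partial.append((policy, vector, index))
    order = sorted(range(len(partial)), key=lambda k: -partial[k][2])
    ranks = {partial[k][0]: r for r, k in enumerate(order, start=1)}
    return [
        PmcResult(
            policy=policy,
            primary_scores=vector,
            pmc_index=index,
            grade=classify(index, scale),
            rank=ranks[policy],
        )
        for policy, vector, index in partial
    ]


def variable_means(results: Sequence[PmcResult]) -> tuple[float, ...]:
    """Cross-policy mean of each primary score, reported to 2 decimals.

    Means are taken over the mode's reported scores, matching how published
    score tables average their printed (2-decimal) columns.
    """
    if not results:
        raise PmcError("no results to average")
    lengths = {len(r.primary_scores) for r in results}
    if len(lengths) != 1:
        raise PmcError("results mix schemas of different primary counts")
    n = len(results)
    sums = [Decimal(0)] * lengths.pop()
    for r in results:
        for i, d in enumerate(r.primary_scores._decimals()):
            sums[i] += d
    return tuple(round_half_up(s / n) for s in sums)


def group_mean(results: Sequence[PmcResult], subset: Iterable[str]) -> float:
    """Mean reported PMC index over *subset* policies, to 2 decimals."""
    subset = list(subset)
    if not subset:
        raise PmcError("empty policy subset")
    by_policy = {r.policy: r for r in results}
    unknown = [p for p in subset if p not in by_policy]
    if unknown:
        raise KeyError(f"policies not in results: {unknown}")
    total = sum(Decimal(f"{by_policy[p].pmc_index:.2f}") for p in subset)
    return round_half_up(total / len(subset))


def improvement_path(
    result: PmcResult, means: Sequence[float]
) -> tuple[int, ...]:
    """Primary indices scoring strictly below the cross-policy mean,
    ordered by gap (mean - score) descending; equal gaps break by
    ascending primary index.

    Returns 1-based primary indices, e.g. ``(3, 1, 9, 8)`` reads
    "improve X3 first, then X1, X9, X8".
    """
    scores = result.primary_scores._decimals()
    if len(means) != len(scores):
        raise PmcError("means length does not match the score vector")
    gaps = []
    for i, (score, mean) in enumerate(zip(scores, means), start=1):
        gap = Decimal(f"{mean:.2f}") - score
        if gap > 0:
            gaps.append((gap, i))
    gaps.sort(key=lambda t: (-t[0], t[1]))
    return tuple(i for _, i in gaps)
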