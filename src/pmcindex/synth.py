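"""Seeded synthetic inputs: score tables and corpora with known structure.

Score tables are independent Bernoulli draws per secondary variable, so a
generated table's statistical shape is fully specified by the per-criterion
success probabilities. The default probabilities are the empirical
per-criterion frequencies of the bundled 10-policy table, i.e. the
generator emulates the observed scoring pattern of China's smart
older-adults-care policies (without their between-criterion dependence,
which no published generative model specifies).

Corpora are built with a planted hub: every co-occurrence unit contains
all hub terms plus uniformly sampled filler terms, which forces the hubs
to dominate the co-occurrence network's weighted degree.

All randomness comes from numpy's ``default_rng`` (the PCG64 bit
generator), so a seed fully determines the output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .schema import EvaluationSchema, builtin_schema
from .scores import ScoreTable, builtin_score_table
from .textmine import Corpus, Document

__all__ = [
    "ScoreGenSpec",
    "CorpusGenSpec",
    "generate_score_table",
    "generate_corpus",
    "empirical_probabilities",
]


def empirical_probabilities(table: ScoreTable | None = None) -> dict[str, float]:
    """Per-secondary bit frequency of *table* (default: the bundled one)."""
    table = table or builtin_score_table()
    return {sid: float(table.values[sid].mean()) for sid in table.schema.secondary_ids}


@dataclass(frozen=True)
class ScoreGenSpec:
    """Specification for a Bernoulli score-table draw.

    ``probabilities`` may be a scalar (broadcast everywhere), a mapping
    keyed by primary id ("X5", broadcast over that primary's criteria) or
    by secondary id ("X53"); omitted entries fall back to ``default_p``.
    With ``probabilities=None`` the bundled table's empirical frequencies
    are used.
    """

    schema: EvaluationSchema = field(default_factory=builtin_schema)
    n_policies: int = 10
    probabilities: float | Mapping[str, float] | None = None
    default_p: float = 0.5
    seed: int = 0

    def resolved_probabilities(self) -> dict[str, float]:
        probs: dict[str, float] = {}
        source = self.probabilities
        if source is None:
            source = empirical_probabilities()
        for primary in self.schema.primaries:
            for sec in primary.secondaries:
                if isinstance(source, (int, float)):
                    p = float(source)
                elif sec.id in source:
                    p = float(source[sec.id])
                elif primary.id in source:
                    p = float(source[primary.id])
                else:
                    p = self.default_p
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"probability {p} for {sec.id} outside [0, 1]")
                probs[sec.id] = p
        return probs


def generate_score_table(spec: ScoreGenSpec) -> ScoreTable:
    """Draw an ``n_policies x n_secondaries`` binary table, one independent
    Bernoulli(p) per cell; identical specs yield identical tables."""
    if spec.n_policies < 0:
        raise ValueError("n_policies must be >= 0")
    spec.schema.validate_structure()
    probs = spec.resolved_probabilities()
    rng = np.random.default_rng(spec.seed)
    ids = list(spec.schema.secondary_ids)
    p_row = np.array([probs[sid] for sid in ids])
    bits = (rng.random((spec.n_policies, len(ids))) < p_row).astype(int)
    values = pd.DataFrame(
        bits,
        index=pd.Index([f"S{k + 1}" for k in range(spec.n_policies)], name="policy"),
        columns=ids,
    )
    return ScoreTable(schema=spec.schema, values=values)


@dataclass(frozen=True)
class CorpusGenSpec:
    """Specification for a planted-hub corpus.

    Every unit contains each hub term once plus ``fillers_per_unit``
    uniform draws (with replacement) from the non-hub vocabulary.
    """

    vocabulary: tuple[str, ...]
    hub_terms: tuple[str, ...] = ()
    n_documents: int = 10
    units_per_document: int = 20
    fillers_per_unit: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(self.hub_terms) - set(self.vocabulary)
        if missing:
            raise ValueError(f"hub terms not in vocabulary: {sorted(missing)}")


def generate_corpus(spec: CorpusGenSpec) -> Corpus:
    """Generate a corpus whose hub terms co-occur with everything.

    By construction every (hub, x) pair co-occurs in each unit where x
    appears, so each hub's weighted degree is at least that of any
    non-hub term.
    """
    if spec.n_documents and spec.units_per_document and not spec.vocabulary:
        raise ValueError("empty vocabulary cannot fill any unit")
    rng = np.random.default_rng(spec.seed)
    fillers = [t for t in spec.vocabulary if t not in set(spec.hub_terms)]
    documents = []
    for d in range(spec.n_documents):
        units = []
        for _ in range(spec.units_per_document):
            unit = list(spec.hub_terms)
            if fillers and spec.fillers_per_unit:
                picks = rng.integers(0, len(fillers), size=spec.fillers_per_unit)
                unit.extend(fillers[i] for i in picks)
            units.append(tuple(unit))
        documents.append(Document(id=f"D{d + 1}", units=tuple(units)))
    return Corpus(documents=tuple(documents))
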