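"""Binary score tables: policies x secondary variables.

The score table is the model's multi-input-output table: one bit per
(policy, criterion) cell, 1 when the policy text satisfies the criterion.
Three interchangeable file dialects are supported:

``long``
    Tidy CSV, one row per cell: ``policy,secondary,value``.
``wide``
    One row per policy, one 0/1 column per secondary id.
``compact``
    The printed layout: one row per primary variable, one column per
    policy, each cell a bitstring over that primary's criteria in schema
    order (e.g. ``"110"``).

All three round-trip losslessly through :func:`read_score_table` /
:func:`write_score_table`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ScoreTableError
from .schema import EvaluationSchema, builtin_schema

__all__ = [
    "ScoreTable",
    "read_score_table",
    "write_score_table",
    "builtin_score_table",
    "DIALECTS",
]

Dialect = Literal["long", "wide", "compact"]
DIALECTS: tuple[str, ...] = ("long", "wide", "compact")


@dataclass
class ScoreTable:
    """Validated binary matrix of policies x secondary variables.

    Attributes
    ----------
    schema
        The indicator system the columns refer to.
    values
        DataFrame indexed by policy code, one int column per secondary id,
        columns in schema order, every cell 0 or 1.
    metadata
        Optional per-policy annotations (name, issuing organ, release
        date, administrative level). Never used in index computation;
        grouping helpers may consume it.
    """

    schema: EvaluationSchema
    values: pd.DataFrame
    metadata: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        self.validate()

    # -- views -----------------------------------------------------------
    @property
    def policies(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_policies(self) -> int:
        return len(self.values)

    def bits(self, policy: str, primary_index: int) -> tuple[int, ...]:
        """The bit vector of one primary variable for one policy."""
        if policy not in self.values.index:
            raise KeyError(f"unknown policy {policy!r}")
        ids = [s.id for s in self.schema.primary(primary_index).secondaries]
        return tuple(int(v) for v in self.values.loc[policy, ids])

    # -- validation ------------------------------------------------------
    def validate(self) -> "ScoreTable":
        violations: list[str] = []
        expected = list(self.schema.secondary_ids)
        got = list(self.values.columns)
        if sorted(got) != sorted(expected):
            missing = sorted(set(expected) - set(got))
            extra = sorted(set(got) - set(expected))
            if missing:
                violations.append(f"missing secondary columns: {missing}")
            if extra:
                violations.append(f"columns not in schema: {extra}")
        else:
            if got != expected:  # normalise column order to schema order
                self.values = self.values[expected]
            frame = self.values
            if frame.isna().any().any():
                for policy, row in frame.iterrows():
                    for sid in frame.columns[row.isna()]:
                        violations.append(f"missing cell ({policy}, {sid})")
            else:
                arr = frame.to_numpy()
                bad = ~np.isin(arr, (0, 1))
                if bad.any():
                    for i, j in zip(*np.nonzero(bad)):
                        violations.append(
                            f"non-binary value {arr[i, j]!r} at "
                            f"({frame.index[i]}, {frame.columns[j]})"
                        )
                else:
                    self.values = frame.astype(int)
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            violations.append(f"duplicate policy codes: {dupes}")
        if violations:
            raise ScoreTableError(violations)
        return self


# ---------------------------------------------------------------------------
# dialect I/O


def _read_text(source: str | Path | io.TextIOBase) -> str:
    if isinstance(source, io.TextIOBase):
        return source.read()
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        return Path(source).read_text(encoding="utf-8")
    return str(source)


def read_score_table(
    source: str | Path | io.TextIOBase,
    schema: EvaluationSchema,
    dialect: Dialect = "long",
    metadata: pd.DataFrame | None = None,
) -> ScoreTable:
    """Parse a score table document in any dialect and validate it.

    Raises
    ------
    ScoreTableError
        For non-binary cells, missing cells, unknown ids, or compact
        bitstrings whose length differs from the primary's criterion count.
    """
    text = _read_text(source)
    if dialect == "long":
        frame = pd.read_csv(io.StringIO(text), dtype={"policy": str, "secondary": str})
        if frame.empty:
            values = pd.DataFrame(columns=list(schema.secondary_ids), dtype=int)
            values.index.name = "policy"
            return ScoreTable(schema, values, metadata)
        dupes = frame.duplicated(subset=["policy", "secondary"])
        if dupes.any():
            pairs = frame.loc[dupes, ["policy", "secondary"]].to_records(index=False)
            raise ScoreTableError([f"duplicate cell {tuple(p)}" for p in pairs])
        values = frame.pivot(index="policy", columns="secondary", values="value")
        values = values.reindex(index=pd.unique(frame["policy"]))
        values.columns.name = None
        for sid in schema.secondary_ids:  # absent cells surface as NaN, not as
            if sid not in values.columns:  # a missing-column complaint
                values[sid] = np.nan
    elif dialect == "wide":
        values = pd.read_csv(io.StringIO(text), index_col="policy", dtype={"policy": str})
    elif dialect == "compact":
        values = _read_compact(text, schema)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    values.index = values.index.astype(str)
    values.index.name = "policy"
    return ScoreTable(schema, values, metadata)


def _read_compact(text: str, schema: EvaluationSchema) -> pd.DataFrame:
    frame = pd.read_csv(io.StringIO(text), index_col="primary", dtype=str)
    violations: list[str] = []
    columns: dict[str, dict[str, int]] = {p: {} for p in frame.columns}
    for primary in schema.primaries:
        row_id = primary.id
        if row_id not in frame.index:
            violations.append(f"missing row for primary {row_id}")
            continue
        for policy in frame.columns:
            bitstring = frame.loc[row_id, policy]
            bitstring = "" if pd.isna(bitstring) else str(bitstring).strip()
            if len(bitstring) != primary.n_secondaries:
                violations.append(
                    f"bitstring {bitstring!r} for ({policy}, {row_id}) has length "
                    f"{len(bitstring)}; expected {primary.n_secondaries}"
                )
                continue
            if set(bitstring) - {"0", "1"}:
                violations.append(f"non-binary bitstring {bitstring!r} for ({policy}, {row_id})")
                continue
            for sec, ch in zip(primary.secondaries, bitstring):
                columns[policy][sec.id] = int(ch)
    extra = set(frame.index) - {p.id for p in schema.primaries}
    if extra:
        violations.append(f"rows not in schema: {sorted(extra)}")
    if violations:
        raise ScoreTableError(violations)
    values = pd.DataFrame.from_dict(columns, orient="index")
    return values.reindex(columns=list(schema.secondary_ids))


def write_score_table(
    table: ScoreTable,
    dest: str | Path | None = None,
    dialect: Dialect = "long",
) -> str:
    """Serialise *table* in the given dialect; write to *dest* if given.

    Returns the document text either way. An empty policy list yields a
    header-only document in every dialect.
    """
    if dialect == "long":
        long = (
            table.values.rename_axis("policy")
            .reset_index()
            .melt(id_vars="policy", var_name="secondary", value_name="value")
        )
        order = {sid: k for k, sid in enumerate(table.schema.secondary_ids)}
        pol_order = {p: k for k, p in enumerate(table.policies)}
        long = long.sort_values(
            by=["policy", "secondary"],
            key=lambda col: col.map(pol_order if col.name == "policy" else order),
            kind="stable",
        )
        text = long.to_csv(index=False)
    elif dialect == "wide":
        text = table.values.to_csv(index_label="policy")
    elif dialect == "compact":
        rows = {}
        for primary in table.schema.primaries:
            ids = [s.id for s in primary.secondaries]
            rows[primary.id] = {
                policy: "".join(str(int(b)) for b in table.values.loc[policy, ids])
                for policy in table.policies
            }
        compact = pd.DataFrame.from_dict(rows, orient="index", dtype=str)
        compact = compact.reindex(columns=table.policies)
        text = compact.to_csv(index_label="primary")
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if dest is not None:
        Path(dest).write_text(text, encoding="utf-8")
    return text


def builtin_score_table(schema: EvaluationSchema | None = None) -> ScoreTable:
    """The packaged scoring of the 10 representative smart older-adults-care
    policies (China, 2019-2024): 10 policies x 33 bits, with per-policy
    metadata (name, issuing organ, release date, administrative level)."""
    schema = schema or builtin_schema()
    data_pkg = resources.files("pmcindex.data")
    scores_text = (data_pkg / "smart_eldercare_scores.csv").read_text(encoding="utf-8")
    meta = pd.read_csv(
        io.StringIO((data_pkg / "smart_eldercare_policies.csv").read_text(encoding="utf-8")),
        index_col="policy",
    )
    return read_score_table(scores_text, schema, dialect="compact", metadata=meta)
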