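"""Evaluation schemas: primary policy dimensions holding binary criteria.

A schema is an ordered list of *primary variables* (policy dimensions such
as "Policy Timeliness"), each holding one or more *secondary variables* —
individual yes/no criteria judged against a policy text. Secondary variables
are equally weighted by construction: no weight field exists anywhere.

Variable ids follow the field's notation: ``X53`` is the 3rd criterion of
primary variable 5. Indices are 1-based throughout.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Iterator

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import SchemaError

__all__ = [
    "SecondaryVariableDef",
    "PrimaryVariableDef",
    "EvaluationSchema",
    "load_schema",
    "builtin_schema",
]


class SecondaryVariableDef(BaseModel):
    """One binary criterion: scored 1 when the policy text satisfies it."""

    model_config = ConfigDict(frozen=True)

    id: str
    label: str = ""
    criterion: str = ""


class PrimaryVariableDef(BaseModel):
    """A policy dimension aggregating equally weighted binary criteria."""

    model_config = ConfigDict(frozen=True)

    index: int = Field(ge=1)
    label: str = ""
    secondaries: tuple[SecondaryVariableDef, ...]

    @property
    def id(self) -> str:
        return f"X{self.index}"

    @property
    def n_secondaries(self) -> int:
        return len(self.secondaries)


class EvaluationSchema(BaseModel):
    """An ordered indicator system of primary variables.

    Construction does not validate cross-variable invariants (duplicate
    ids, id/position mismatches); call :meth:`validate_structure` or go
    through :func:`load_schema`, which enumerates every violation at once.
    """

    model_config = ConfigDict(frozen=True)

    name: str = ""
    primaries: tuple[PrimaryVariableDef, ...]

    # -- views -----------------------------------------------------------
    @property
    def n_primaries(self) -> int:
        return len(self.primaries)

    @property
    def n_secondaries(self) -> int:
        return sum(p.n_secondaries for p in self.primaries)

    @property
    def secondary_ids(self) -> tuple[str, ...]:
        """All secondary ids in schema order (primary order, then position)."""
        return tuple(s.id for p in self.primaries for s in p.secondaries)

    def primary(self, index: int) -> PrimaryVariableDef:
        for p in self.primaries:
            if p.index == index:
                return p
        raise KeyError(f"no primary variable with index {index}")

    def iter_secondaries(self) -> Iterator[tuple[PrimaryVariableDef, SecondaryVariableDef]]:
        for p in self.primaries:
            for s in p.secondaries:
                yield p, s

    # -- validation ------------------------------------------------------
    def structure_violations(self) -> list[str]:
        """Every invariant violation in the schema, in document order."""
        violations: list[str] = []
        if not self.primaries:
            violations.append("schema has no primary variables")
        seen_primary: set[int] = set()
        seen_ids: set[str] = set()
        for p in self.primaries:
            if p.index in seen_primary:
                violations.append(f"duplicate primary index {p.index}")
            seen_primary.add(p.index)
            if not p.secondaries:
                violations.append(f"primary X{p.index} has no secondary variables")
            for pos, s in enumerate(p.secondaries, start=1):
                expected = f"X{p.index}{pos}"
                if s.id != expected:
                    violations.append(
                        f"secondary id {s.id!r} does not match its position; expected {expected!r}"
                    )
                if s.id in seen_ids:
                    violations.append(f"duplicate secondary id {s.id!r}")
                seen_ids.add(s.id)
        return violations

    def validate_structure(self) -> "EvaluationSchema":
        violations = self.structure_violations()
        if violations:
            raise SchemaError(violations)
        return self

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "primaries": [
                {
                    "index": p.index,
                    "label": p.label,
                    "secondaries": [
                        {"id": s.id, "label": s.label, "criterion": s.criterion}
                        for s in p.secondaries
                    ],
                }
                for p in self.primaries
            ],
        }


def load_schema(source: str | Path | dict[str, Any]) -> EvaluationSchema:
    """Load and validate an evaluation schema from YAML/JSON.

    Parameters
    ----------
    source
        A path to a ``.yaml``/``.json`` document, a document string, or an
        already-parsed mapping with keys ``name`` and ``primaries``.

    Raises
    ------
    SchemaError
        Listing *all* structural violations (duplicate ids, empty
        secondary lists, ids that do not encode their position).
    """
    if isinstance(source, dict):
        raw = source
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            text = Path(source).read_text(encoding="utf-8")
        else:
            text = str(source)
        raw = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(raw, dict) or "primaries" not in raw:
        raise SchemaError(["document does not contain a 'primaries' list"])
    schema = EvaluationSchema.model_validate(raw)
    return schema.validate_structure()


def builtin_schema() -> EvaluationSchema:
    """The packaged smart older-adults-care indicator system.

    Nine primary variables — Policy Nature (X1), Area (X2), Timeliness
    (X3), Aim (X4), Content (X5), Object (X6), Evaluation (X7), Measure
    (X8) and Tool (X9) — holding 33 binary criteria in total, with
    secondary counts (3, 3, 3, 3, 5, 4, 3, 5, 4).
    """
    ref = resources.files("pmcindex.data") / "smart_eldercare_schema.yaml"
    return load_schema(yaml.safe_load(ref.read_text(encoding="utf-8")))


def _schema_to_yaml(schema: EvaluationSchema) -> str:
    return yaml.safe_dump(schema.to_dict(), sort_keys=False, allow_unicode=True)


def _schema_to_json(schema: EvaluationSchema) -> str:
    return json.dumps(schema.to_dict(), ensure_ascii=False, indent=2)
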