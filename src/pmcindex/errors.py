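"""Exception types shared across the toolkit."""

from __future__ import annotations


class PmcError(Exception):
    """Base class for all toolkit errors."""


class SchemaError(PmcError):
    """An evaluation schema violates its invariants.

    Carries the full list of violations so callers can report every
    problem at once instead of fixing them one at a time.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ScoreTableError(PmcError):
    """A score table is malformed: non-binary cells, missing cells,
    unknown variable ids, or bitstrings of the wrong length."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))
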