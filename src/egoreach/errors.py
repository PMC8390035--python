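"""Exception hierarchy for the egoreach pipeline."""

from __future__ import annotations


class EgoreachError(Exception):
    """Base class for all egoreach errors."""


class SchemaError(EgoreachError):
    """A required column or configuration entry is missing or malformed."""


class RecodeError(EgoreachError):
    """A category label could not be mapped to a canonical level."""


class MicrodataError(EgoreachError):
    """One or more microdata rows failed validation.

    Carries every failure so that bad rows are reported, never silently
    dropped.
    """

    def __init__(self, failures: list[tuple[object, str]]):
        self.failures = list(failures)
        lines = [f"  row {row}: {msg}" for row, msg in self.failures[:50]]
        extra = len(self.failures) - len(lines)
        if extra > 0:
            lines.append(f"  ... and {extra} more")
        super().__init__(
            f"{len(self.failures)} microdata row(s) failed validation:\n" + "\n".join(lines)
        )


class ParameterError(EgoreachError):
    """Invalid generator parameters."""


class DataError(EgoreachError):
    """A record is inconsistent with the analysis contracts (e.g. a kin role
    outside the ego's role set)."""


class ConsistencyError(EgoreachError):
    """Cross-definition state that violates network nesting."""


class UsageError(EgoreachError):
    """An operation was called with arguments outside its contract."""
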