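"""Exception hierarchy for kgpathrank.

All package-specific failures derive from :class:`KgError` so callers can
catch one base class at API boundaries (the CLI does exactly that).
"""


class KgError(Exception):
    """Base class for all kgpathrank errors."""


class ConflictError(KgError):
    """Two definitions of the same entity (or mapping target) disagree."""


class ReferentialError(KgError):
    """An edge references an entity that is not in the graph."""


class SelfLoopError(KgError):
    """An edge with identical head and tail was rejected."""


class EntityNotFoundError(KgError, KeyError):
    """Lookup of an unknown entity id."""


class FormatError(KgError):
    """A source stream violates its declared file format.

    Carries an optional 1-based line number for diagnostics.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PathParseError(KgError):
    """A printed path record does not match the node--label--node syntax."""


class QueryError(KgError):
    """An invalid path or graph query (e.g. source equals target)."""


class ParameterError(KgError):
    """A parameter outside its documented domain."""


class PlanError(KgError):
    """A synthetic fixture plan is internally inconsistent or infeasible."""
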