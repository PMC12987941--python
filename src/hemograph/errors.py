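"""Exception hierarchy.

Every error raised on purpose by this package derives from
:class:`HemographError`, so callers can catch the package's failures
without swallowing programming errors.
"""


class HemographError(Exception):
    """Base class for all errors raised by hemograph."""


class FormatError(HemographError):
    """A file could not be parsed, or a required named field is absent."""


class StructuralError(HemographError):
    """Mesh connectivity or container shape violates an invariant."""


class GeometryError(HemographError):
    """A geometric precondition failed (non-planar inlet, inverted cell, ...)."""


class ConfigurationError(HemographError):
    """Inconsistent or overlapping user configuration."""


class DomainError(HemographError):
    """Requested points/planes fall outside the mesh domain."""


class EmptySliceError(DomainError):
    """A cutting plane does not intersect the mesh."""


class TrainingDivergedError(HemographError):
    """Loss became non-finite during optimization."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
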