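"""Exception hierarchy shared across the package."""


class GirkpermError(Exception):
    """Base class for all girkperm errors."""


class ParseError(GirkpermError):
    """Malformed input file; message carries the offending line number."""


class SelectionError(GirkpermError):
    """Syntactically invalid atom-selection expression."""


class SpecError(GirkpermError):
    """Inconsistent synthetic-data specification."""


class DefinitionError(GirkpermError):
    """Selectivity-filter definition cannot be resolved on the topology."""


class DegeneracyError(GirkpermError):
    """Numerically degenerate geometry (collinear/coincident fit atoms)."""


class DataError(GirkpermError):
    """Input data violates a precondition (range, sign-change, shape)."""


class FitError(GirkpermError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate
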