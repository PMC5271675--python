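"""Exception hierarchy for dyncomp."""


class DyncompError(Exception):
    """Base class for all dyncomp errors."""


class FormatError(DyncompError):
    """Input file is malformed or inconsistent (e.g. atom-count mismatch)."""


class EmptyInputError(DyncompError):
    """Input contains no usable frames or series."""


class ValidationError(DyncompError):
    """Arguments or domain objects violate a documented contract."""


class SelectionError(DyncompError):
    """An atom selection is empty or otherwise unusable for a residue."""


class UndefinedCorrelationError(DyncompError):
    """Correlation requested for a zero-variance series."""


class FitError(DyncompError):
    """No usable mixture fit could be obtained for a series."""


class ConsistencyError(DyncompError):
    """Internal cross-references do not resolve (e.g. residue absent from frame)."""


class GenerationError(DyncompError):
    """Synthetic-data spec is geometrically or logically infeasible."""
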