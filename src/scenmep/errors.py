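"""Exception hierarchy shared across the package.

Every stage raises a subclass of :class:`ScenmepError` so pipeline callers
can attach stage context without catching bare exceptions.
"""


class ScenmepError(Exception):
    """Base class for all package errors."""


class SchemaError(ScenmepError):
    """A table is missing mandatory columns or has the wrong shape."""


class ValidationError(ScenmepError):
    """Row-level content violates the schema (bad enum label, NaN, ...)."""


class ConfigurationError(ScenmepError):
    """A gate, coupling or pipeline configuration is inconsistent."""


class DegenerateWellError(ScenmepError):
    """A SCENITH well set has no usable background window (C <= DGO)."""


class InsufficientDataError(ScenmepError):
    """Too few cells/donors/timepoints for the requested computation."""


class DegenerateFitError(ScenmepError):
    """A regression predictor has zero variance."""
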