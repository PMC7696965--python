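"""Exception hierarchy shared across the package.

Everything derives from :class:`OralFusionError` so callers can catch the
package's failures in one clause; the subclasses mirror the distinct failure
modes of the pipeline stages (bad study design, degenerate numerics, mismatched
sample bookkeeping, ...).
"""


class OralFusionError(Exception):
    """Base class for all errors raised by oralfusion."""


class InvalidSpecError(OralFusionError, ValueError):
    """A cohort/effect specification violates its invariants."""


class NonUniformGridError(OralFusionError, ValueError):
    """An operation requiring an evenly spaced wavenumber axis got an uneven one."""


class CoverageError(OralFusionError, ValueError):
    """A spectrum does not cover the requested wavenumber range."""


class DegenerateInputError(OralFusionError, ValueError):
    """Input carries no usable signal (constant spectrum, zero variance, ...)."""


class DimensionMismatchError(OralFusionError, ValueError):
    """Feature dimensions do not match between a fitted model and new data."""


class AlignmentError(OralFusionError, ValueError):
    """Sample identifiers cannot be matched across modalities."""


class UndefinedMetricError(OralFusionError, ValueError):
    """A performance metric has a zero denominator; the message names the metric."""


class FoldError(OralFusionError, ValueError):
    """A cross-validation fold is unusable (e.g. a training fold lost a class)."""


class StageError(OralFusionError, RuntimeError):
    """A pipeline stage failed; the message carries the stage name and sample id."""
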