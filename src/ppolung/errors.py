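"""Exception hierarchy for the ppolung pipeline.

All pipeline errors derive from :class:`PpolungError` so callers can catch the
package's failures without masking programming errors.
"""


class PpolungError(Exception):
    """Base class for all ppolung errors."""


class ParameterError(PpolungError, ValueError):
    """An argument value is outside its documented domain."""


class ShapeError(PpolungError, ValueError):
    """Two gridded inputs that must share a grid do not."""


class DegenerateInputError(PpolungError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. zero total counts, zero variance)."""


class InsufficientDataError(PpolungError, ValueError):
    """Too few records/pairs to compute the requested statistic."""


class DegenerateAnatomyError(PpolungError, ValueError):
    """A lung-field mask does not contain the expected two-lung anatomy."""


class OpenBoundaryError(PpolungError, ValueError):
    """A fissure trace does not span the lung cross-section on its slice."""


class TraceInconsistencyError(PpolungError, ValueError):
    """Fissure traces contradict each other (duplicates or crossings)."""


class ValidationError(PpolungError, ValueError):
    """A file's content violates its documented schema."""
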