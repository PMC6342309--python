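"""Exception hierarchy for the lungheq pipeline.

Every stage raises a subclass of :class:`LungHeqError` so callers (and the
command-line driver) can distinguish pipeline failures from programming bugs.
"""


class LungHeqError(Exception):
    """Base class for all pipeline errors."""


class FormatError(LungHeqError):
    """An input file could not be parsed in the expected format."""


class GeometryError(LungHeqError):
    """Image and mask geometry disagree (shape, slice count, spacing)."""


class ValidationError(LungHeqError):
    """A value violates a domain invariant (HU range, LAA% bounds, ...)."""


class SchemaError(LungHeqError):
    """A cohort table is missing mandatory canonical columns."""


class DegenerateInputError(LungHeqError):
    """Input is structurally valid but unusable (empty mask, one-class outcome)."""


class ConvergenceError(LungHeqError):
    """A maximum-likelihood fit failed to converge (possibly separation)."""


class CapacityError(LungHeqError):
    """A phantom spec requests more geometry than the grid can hold."""
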