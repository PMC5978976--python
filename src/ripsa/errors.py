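"""Exception hierarchy shared across the package."""


class RipsaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RipsaError, ValueError):
    """An event log record or config violates the documented schema."""


class ParseError(RipsaError, ValueError):
    """A field could not be converted to its declared type."""


class GeometryError(RipsaError, ValueError):
    """A beam/phantom configuration is physically inconsistent."""


class ExtrapolationError(RipsaError, ValueError):
    """A lookup key fell outside the tabulated hull.

    Silent clamping of dosimetric tables is a classic source of wrong
    doses, so out-of-hull queries always raise.
    """


class InfeasibleError(RipsaError, ValueError):
    """A requested target (e.g. HVL below the unfiltered beam's) cannot be met."""


class ConvergenceError(RipsaError, RuntimeError):
    """A root search failed to bracket or converge."""


class QualityError(RipsaError, ValueError):
    """A Monte Carlo tally's statistical quality is too poor to use."""
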