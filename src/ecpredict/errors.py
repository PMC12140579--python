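"""Exception hierarchy shared across the pipeline."""


class EcpredictError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EcpredictError):
    """Invalid run configuration or operation parameters."""


class FormatError(EcpredictError):
    """Malformed input file (reported with line number where possible)."""


class ResolutionError(EcpredictError):
    """Time grid too coarse to resolve the requested events."""


class DegenerateSubjectError(EcpredictError):
    """A subject has no usable trials or data."""


class DegenerateDesignError(EcpredictError):
    """Design matrix cannot be built (e.g. constant covariate)."""


class DegenerateDataError(EcpredictError):
    """Data carry no variance where variance is required."""


class DegenerateTargetError(EcpredictError):
    """Regression target is constant within a training fold."""


class DegenerateNodeError(EcpredictError):
    """A node time series is constant where correlation is required."""


class InstabilityError(EcpredictError):
    """Neural dynamics diverge (unstable coupling matrix)."""


class NumericalError(EcpredictError):
    """Non-finite or nonphysical values encountered during integration."""


class AlignmentError(EcpredictError):
    """Mismatched shapes/orderings between subject-level objects."""
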