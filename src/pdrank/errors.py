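"""Exception hierarchy shared across the package."""


class PdrankError(Exception):
    """Base class for all package-specific errors."""


class DegenerateSampleError(PdrankError, ValueError):
    """Raised when a sample has no usable spread (all values identical)."""


class ParameterError(PdrankError, ValueError):
    """Raised for out-of-range method parameters (levels, fractions, k)."""


class ConfigurationError(PdrankError, ValueError):
    """Raised for unknown kernel ids, bandwidth methods or shape ids."""


class MultimodalError(PdrankError, ValueError):
    """Raised when a single-interval MPR is requested on a multimodal curve.

    Callers should use :func:`pdrank.mpr.most_probable_intervals` instead.
    """


class EmptySampleError(PdrankError, ValueError):
    """Raised when cleaning or parsing leaves no observations."""
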