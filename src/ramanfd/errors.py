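"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes (usage 2, validation 3,
insufficient data 4); library users catch them directly.
"""


class RamanFDError(Exception):
    """Base class for all package errors."""


class ParseError(RamanFDError, ValueError):
    """A spectrum or manifest file could not be parsed."""


class ValidationError(RamanFDError, ValueError):
    """An input violates a structural invariant (duplicate axis values,
    mismatched metadata, mask shape, ...)."""


class RangeError(RamanFDError, ValueError):
    """A requested wavenumber window falls outside the available axis."""


class DegenerateInputError(RamanFDError, ValueError):
    """The input is formally valid but carries no usable signal
    (constant spectrum, single hue category, zero-variance design)."""


class InsufficientDataError(RamanFDError, ValueError):
    """Fewer usable points than the operation's minimum (e.g. < 3
    included excitations for a dispersion fit)."""


class ConfigurationError(RamanFDError, ValueError):
    """A simulation or pipeline configuration is self-inconsistent."""
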