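"""Exception hierarchy shared across the package."""


class KokwaveError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KokwaveError, ValueError):
    """An input object violates one of its declared invariants."""


class DegenerateInputError(KokwaveError, ValueError):
    """Input carries no usable signal (constant, all-zero, or zero-RMS)."""


class SeparabilityError(KokwaveError, RuntimeError):
    """The spectrum does not split into enough bands to isolate the
    period-two mode from the period-four component."""


class InsufficientDataError(KokwaveError, ValueError):
    """Too few flashes for the requested operation."""


class FormatError(KokwaveError, ValueError):
    """A file does not conform to the expected tabular layout."""
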