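"""Exception hierarchy shared across the package."""


class MxScreenError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(MxScreenError, ValueError):
    """An argument violates a documented precondition."""


class StateExhaustedError(MxScreenError, RuntimeError):
    """The covering search was asked to continue after all pairs were covered."""


class MissingControlError(MxScreenError, ValueError):
    """A normalization stratum has no usable vehicle-control wells."""


class InsufficientDataError(MxScreenError, ValueError):
    """Too few observations to evaluate the requested statistic or fit."""


class IncompleteInputError(MxScreenError, ValueError):
    """A required companion measurement (e.g. a single-agent value) is absent."""


class SchemaError(MxScreenError, ValueError):
    """A file does not conform to the declared CSV/JSON dialect."""
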