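"""Exception hierarchy used across the package.

All user-facing errors derive from :class:`CapfitError` so that callers
(and the CLI) can distinguish bad inputs (exit code 2) from numerical
failures (exit code 3).
"""


class CapfitError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CapfitError, ValueError):
    """A physically or structurally invalid argument was supplied."""


class ConfigurationError(CapfitError, ValueError):
    """A configuration file or run configuration failed validation."""


class SignalParseError(CapfitError, ValueError):
    """A sampled-signal file could not be parsed into a uniform grid."""


class DivergenceError(CapfitError, ArithmeticError):
    """A simulated trajectory became non-finite.

    Attributes
    ----------
    blow_up_time : float
        First time at which a non-finite value was observed.
    """

    def __init__(self, message: str, blow_up_time: float):
        super().__init__(message)
        self.blow_up_time = blow_up_time
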