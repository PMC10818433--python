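"""Exception hierarchy shared across the package."""


class RespvitError(Exception):
    """Base class for all package-specific errors."""


class InputFormatError(RespvitError, ValueError):
    """An input file could not be read or parsed (bad WAV, malformed annotation row)."""


class ParameterError(RespvitError, ValueError):
    """A parameter violates its documented domain (negative rate, bad filterbank geometry...)."""


class ConfigurationError(RespvitError, ValueError):
    """Model / training configuration is internally inconsistent with the data."""


class NumericError(RespvitError, ArithmeticError):
    """Non-finite activations or other numerical breakdown during model evaluation."""
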