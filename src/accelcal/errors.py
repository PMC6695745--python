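"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class AccelCalError(Exception):
    """Base class for all package errors."""


class ConfigError(AccelCalError):
    """Invalid configuration or parameters."""


class DataError(AccelCalError):
    """Malformed or inconsistent input data."""


class UpsamplingError(ConfigError):
    """Requested resampling rate above the source rate."""


class InvalidBandError(ConfigError):
    """Band-pass corner frequencies incompatible with the sample rate."""


class ExtrapolationError(AccelCalError):
    """A cut-point lies above the fitted curve's maximum; refusing to extrapolate."""
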