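"""Exception types shared across the package.

Three failure categories are distinguished so callers (and the CLI) can
report them differently: bad configuration values, malformed or
inconsistent data, and invalid arguments to an operation.
"""


class NemacgeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NemacgeError, ValueError):
    """A configuration value is out of range or inconsistent."""


class DataError(NemacgeError, ValueError):
    """Input data violate a documented contract (unknown neuron, duplicate edge, ...)."""


class ArgumentError(NemacgeError, ValueError):
    """An operation was called with an invalid argument."""
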