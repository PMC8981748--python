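"""Exception hierarchy; CLI exit codes map onto these classes."""


class PairriskError(Exception):
    """Base class for all pairrisk errors."""

    exit_code = 1


class ConfigError(PairriskError):
    """Invalid configuration or parameter values."""

    exit_code = 2


class DataError(PairriskError):
    """Malformed, inconsistent, or degenerate input data."""

    exit_code = 3


class ModelIOError(DataError):
    """Model file cannot be parsed or has an incompatible version."""


class ConvergenceError(PairriskError):
    """An iterative fit failed to converge."""

    exit_code = 4
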