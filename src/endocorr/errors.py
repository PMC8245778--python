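"""Exception hierarchy with CLI exit codes.

Data errors (malformed or inconsistent input values) exit with 2,
configuration errors (bad parameters, missing files, impossible settings)
with 3, everything else with 1.
"""


class EndocorrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DataError(EndocorrError):
    """Invalid input data: malformed files, out-of-range values, bad ids."""

    exit_code = 2


class ConfigError(EndocorrError):
    """Invalid configuration or parameters."""

    exit_code = 3


class FitError(EndocorrError):
    """Model fitting failed (non-convergence, monotone likelihood)."""

    exit_code = 1
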