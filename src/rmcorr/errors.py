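"""Exception hierarchy.

Every error raised by this package derives from :class:`RmcorrError`.  The
three branches map onto distinct CLI exit codes: configuration mistakes
(bad arguments, missing columns) exit 2, data problems (too few
participants, non-finite values) exit 3, and numerical/degenerate-design
failures exit 4.
"""


class RmcorrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigurationError(RmcorrError):
    """Invalid user input: unknown column, bad option value, malformed spec."""

    exit_code = 2


class DataError(RmcorrError):
    """The data violate a structural requirement of the method."""

    exit_code = 3


class DataInsufficiencyError(DataError):
    """Too little data: N < 2, fewer than 2 pairs per participant, or df < 1."""


class NumericError(RmcorrError):
    """Numerical failure or degenerate design encountered while fitting."""

    exit_code = 4


class DegenerateDesignError(NumericError):
    """No within-participant variance in the covariate anywhere in the data."""


class ConsistencyError(NumericError):
    """A fitted result was paired with data it was not fitted on."""
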