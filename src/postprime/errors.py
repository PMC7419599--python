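"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class PostprimeError(Exception):
    """Base class for all package errors."""


class ConfigError(PostprimeError):
    """Invalid configuration value; the message names the offending field."""


class DataError(PostprimeError):
    """Input data violates a schema or a precondition."""


class UnanalyzableTrialError(DataError):
    """A trial on which a required event could not be found."""


class DegenerateBaselineError(DataError):
    """Baseline SD is zero while the signal is not flat."""


class DeadChannelError(DataError):
    """An all-zero EMG channel cannot be max-normalized."""


class MissingCellError(DataError):
    """A participant is missing one or more condition cells."""


class DegenerateDataError(DataError):
    """Zero error variance makes the requested F statistic undefined."""


class PosthocRefusedError(PostprimeError):
    """Post hoc comparisons requested without a significant omnibus effect."""
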