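"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses)
to exit code 3.
"""


class RecruitplotError(Exception):
    """Base class for all package errors."""


class ConfigError(RecruitplotError):
    """Invalid configuration: bad parameter values, missing paths."""


class DataError(RecruitplotError, ValueError):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """A record in an input file could not be parsed."""


class InsufficientDepthError(DataError):
    """An operation was requested on a profile with too few reads."""
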