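"""Exception hierarchy.

Every error raised by the package derives from :class:`SweepscanError` so
callers (and the CLI) can distinguish user/input problems from genuine bugs.
"""


class SweepscanError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SweepscanError, ValueError):
    """Invalid configuration: bad parameter values, inconsistent settings."""


class FormatError(SweepscanError, ValueError):
    """Malformed input file (VCF, BED, sample map, term table)."""


class DomainError(SweepscanError, ValueError):
    """Operation called outside its mathematical domain (e.g. n < 2)."""


class UnknownLabelError(SweepscanError, KeyError):
    """A population, sample or gene label is not present in the data."""
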