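"""Exception hierarchy shared by all pipeline stages.

The command-line layer maps these onto exit codes:
usage/configuration errors -> 1, data errors -> 2, quality errors -> 3.
"""


class NmcdiError(Exception):
    """Base class for all package errors."""


class UsageError(NmcdiError):
    """The caller invoked an operation with inconsistent arguments."""


class ConfigError(UsageError):
    """A configuration file or parameter set failed validation."""


class ParameterError(UsageError):
    """A numeric parameter is outside its admissible range."""


class DataError(NmcdiError):
    """Input data violate a structural precondition (non-monotone time,
    disjoint spans, missing overlap...)."""


class QualityError(NmcdiError):
    """A signal is unusable for the requested computation (no beats,
    no peak above baseline, undefined SNR...)."""


class DetectionError(QualityError):
    """A peak/onset/offset could not be located where one was required."""
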