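"""Exception hierarchy shared across the package.

Separating malformed input (:class:`FormatError`) from well-formed but
internally inconsistent input (:class:`ValidationError`) lets the command-line
layer map them onto distinct exit codes.
"""


class BayesRiskError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BayesRiskError):
    """A file could not be parsed: missing header, wrong columns, empty file."""


class ValidationError(BayesRiskError):
    """Parsed input violates a model invariant (counts, proportions, joins)."""


class DomainError(ValueError, BayesRiskError):
    """A numeric argument is outside the mathematical domain of an operation."""


class ConfigError(BayesRiskError):
    """A configuration object is internally inconsistent."""
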