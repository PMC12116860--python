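"""Exception hierarchy for the asep package.

All data-facing errors derive from :class:`AsepError` so callers (and the
CLI) can distinguish bad inputs from genuine bugs.
"""


class AsepError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AsepError, ValueError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ValidationError(AsepError, ValueError):
    """A table row violates a data-model invariant (bad value, duplicate key)."""


class UndefinedAsepError(AsepError, ValueError):
    """ASEP is undefined because total energy is zero."""


class UndefinedProportionError(AsepError, ValueError):
    """A recipe proportion is undefined (zero non-water, non-trace mass)."""


class EstimationError(AsepError, RuntimeError):
    """A variability estimate cannot be formed from the data at hand."""


class ParameterError(AsepError, ValueError):
    """A method parameter is outside its valid domain."""
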