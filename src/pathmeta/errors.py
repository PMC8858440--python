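"""Exception hierarchy.

Everything raised on purpose by this package derives from :class:`PathmetaError`,
so callers (and the CLI) can catch one type and attribute the failure to a
stage/file.
"""


class PathmetaError(Exception):
    """Base class for all errors raised by pathmeta."""


class ModelFormatError(PathmetaError):
    """A metabolic-model file could not be parsed under the declared format."""


class ModelValidationError(PathmetaError):
    """A parsed model violates an invariant (dangling ids, empty pathways...)."""


class DialectError(PathmetaError):
    """A peak-list file does not provide the columns its dialect requires."""


class RowParseError(PathmetaError):
    """A data row holds a non-numeric value where a number is required."""


class ParameterError(PathmetaError):
    """A user parameter is outside its stated domain."""


class ConfigurationError(PathmetaError):
    """Run configuration is inconsistent (no adduct rules for a mode, ...)."""


class MetaAnalysisError(PathmetaError):
    """A meta-analysis stage failed; message carries study attribution."""
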