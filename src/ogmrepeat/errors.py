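"""Exception hierarchy shared across the package."""


class OgmRepeatError(Exception):
    """Base class for all package-specific errors."""


class FormatError(OgmRepeatError):
    """A file does not conform to its expected format (e.g. missing column)."""


class ParseError(OgmRepeatError):
    """A field within an otherwise well-formed file could not be parsed."""


class EmptyInputError(OgmRepeatError):
    """An input contained no usable records."""


class ValidationError(OgmRepeatError):
    """A value violates a documented constraint."""


class ConsistencyError(OgmRepeatError):
    """Cross-file references do not resolve (e.g. alignment to missing map)."""


class LocusResolutionError(OgmRepeatError):
    """Locus marker positions could not be matched to reference label sites."""


class InsufficientDataError(OgmRepeatError):
    """Too few observations for the requested operation."""


class AllOutliersError(OgmRepeatError):
    """Density filtering removed every observation; epsilon needs inspection."""


class DegenerateDataError(OgmRepeatError):
    """Data carry no variance, so a multi-component fit is undefined."""


class SingularDesignError(OgmRepeatError):
    """Regression design matrix is singular (e.g. constant predictor)."""
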