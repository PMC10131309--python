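"""Exception hierarchy shared across the package.

All errors derive from :class:`SasmoteError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
distinguish the contract that was violated.
"""


class SasmoteError(Exception):
    """Base class for all errors raised by this package."""


class DataFormatError(SasmoteError, ValueError):
    """A feature cell could not be parsed as a number."""


class MissingDataError(SasmoteError, ValueError):
    """A feature value is missing or non-finite.

    Missing values are rejected, never imputed: the resampler operates on
    Euclidean geometry and has no principled imputation story.
    """


class DegenerateLabelsError(SasmoteError, ValueError):
    """Fewer than two classes present in the label column."""


class AmbiguousMinorityError(SasmoteError, ValueError):
    """The two classes are exactly tied and no minority was designated."""


class ConfigurationError(SasmoteError, ValueError):
    """A resampler or generator parameter is outside its valid range."""
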