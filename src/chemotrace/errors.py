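"""Exception hierarchy shared across the package."""


class ChemotraceError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(ChemotraceError):
    """A data file violates its documented format (symbols, shape, header)."""


class ConfigurationError(ChemotraceError):
    """A policy, library, or scenario configuration is inconsistent."""


class RankLookupError(ChemotraceError, LookupError):
    """A taxon filter names a rank value not present in the data."""


class CharacterLookupError(ChemotraceError, LookupError):
    """A requested character is not in the character matrix."""


class TreeFormatError(ChemotraceError):
    """Malformed Newick/NEXUS input or invalid tree structure."""


class BindingError(ChemotraceError):
    """Tree leaves and character-matrix taxa cannot be reconciled."""


class RetentionIndexRangeError(ChemotraceError):
    """Retention time outside the alkane ladder span (no extrapolation)."""


class OracleSizeError(ChemotraceError):
    """Exhaustive enumeration refused: instance too large."""
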