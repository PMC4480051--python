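"""Exception hierarchy.

Every error raised by the library derives from :class:`PlastgapError`; the
CLI maps subfamilies onto distinct exit codes (usage=2, parse=3,
consistency=4, environment=5).
"""


class PlastgapError(Exception):
    """Base class for all library errors."""


class ParseError(PlastgapError):
    """A file could not be parsed in the named format."""


class AlignmentShapeError(ParseError):
    """Rows of an alignment have unequal lengths."""


class DuplicateTaxonError(ParseError):
    """Two rows share the same taxon label."""


class ConsistencyError(PlastgapError):
    """Inputs that must agree (taxa, coordinates, leaf sets) do not."""


class BoundsError(ConsistencyError):
    """A coordinate interval falls outside the alignment."""


class UndefinedComparisonError(ConsistencyError):
    """A pairwise comparison has zero comparable columns."""


class UndefinedCharacterError(ConsistencyError):
    """A character has no non-missing state on the tree."""


class OutgroupError(ConsistencyError):
    """The requested outgroup cannot root the tree (not separable)."""


class ConfigurationError(PlastgapError):
    """Invalid run configuration (empty pool, bad iteration count, ...)."""


class BackendError(PlastgapError):
    """An external inference backend is missing or failed."""


class DataError(PlastgapError):
    """Input data unusable for the requested computation."""


class DensityError(DataError):
    """Requested indel density cannot be placed without overlap."""
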