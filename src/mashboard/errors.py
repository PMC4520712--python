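"""Exception hierarchy.

Every error raised by the library derives from :class:`MashboardError` so
callers (and the CLI) can catch one type.
"""


class MashboardError(Exception):
    """Base class for all mashboard errors."""


class SchemaError(MashboardError):
    """The column-role schema does not match the CSV (e.g. missing geo column)."""


class IngestError(MashboardError):
    """Fatal problem while reading or serializing a marginal dataset."""


class CollisionError(MashboardError):
    """A variable name is defined by more than one dataset."""


class FusionError(MashboardError):
    """The pool cannot be built (e.g. a county lacks the population variable)."""


class IntegrationError(MashboardError):
    """A variable cannot be integrated into the pool for a named county."""


class FilterError(MashboardError):
    """Invalid filter-engine operation (type mismatch, unknown dimension)."""


class LimitError(FilterError):
    """The configured maximum number of simultaneous views was exceeded."""


class QueryError(MashboardError):
    """Malformed or unresolvable API query string."""


class CohortError(MashboardError):
    """Invalid cohort specification or anchored-dataset operation."""
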