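"""Exception hierarchy for geocna.

All library errors derive from :class:`GeocnaError` so callers can catch one
base class at pipeline boundaries.
"""


class GeocnaError(Exception):
    """Base class for all geocna errors."""


class SchemaError(GeocnaError):
    """A declared column or factor is missing or misdeclared."""


class IntegrityError(GeocnaError):
    """Duplicate case identifiers or otherwise inconsistent table state."""


class TableParseError(GeocnaError):
    """A value could not be parsed; message names the row and column."""


class DomainError(GeocnaError):
    """A value lies outside the mathematical domain of an operation."""


class DegeneracyError(GeocnaError):
    """A factor or outcome is constant and cannot be calibrated/analyzed."""


class UndefinedMetricError(GeocnaError):
    """Consistency or coverage requested on an empty reference set."""


class SearchExhaustedError(GeocnaError):
    """Threshold search hit the floor without finding enough configurations."""


class NoCandidatesError(GeocnaError):
    """Model building was given an empty condition table."""


class JoinError(GeocnaError):
    """A geographic join found no overlap between keys."""


class GenerationError(GeocnaError):
    """A synthetic specification could not be satisfied."""
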