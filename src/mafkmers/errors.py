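"""Exception hierarchy shared across the package.

Every error a user can trigger derives from :class:`MafKmersError` so the CLI
can map failure classes to stable exit codes.
"""


class MafKmersError(Exception):
    """Base class for all package errors."""


class MafParseError(MafKmersError):
    """Malformed MAF content; the message names the offending line number."""


class CapacityError(MafKmersError):
    """A hard format limit was exceeded (e.g. >256 genomes in the 8-bit ID field)."""


class RangeError(MafKmersError, ValueError):
    """A k value or code outside the alphabet's supported range."""


class ConsistencyError(MafKmersError):
    """Paired data disagree (e.g. quality string length != sequence length)."""


class ExpressionError(MafKmersError):
    """Malformed or unresolvable count-filter expression."""


class QueryError(MafKmersError):
    """A database query with the wrong length or unencodable symbols."""


class FormatError(MafKmersError):
    """A binary database file failed a structural check."""
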