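"""Exception hierarchy for streakscan.

All errors derive from :class:`StreakscanError` so callers can catch the
package's failures with a single except clause; the concrete subclasses
mirror the failure modes of each stage (parsing, coordinate bounds,
reference consistency, statistical degeneracy).
"""


class StreakscanError(Exception):
    """Base class for all streakscan errors."""


class ParseError(StreakscanError):
    """A file or string could not be parsed (bad VCF record, malformed
    consensus token, unreadable JASPAR block)."""


class BoundsError(StreakscanError):
    """A genomic position falls outside the sequence it refers to."""


class ConsistencyError(StreakscanError):
    """Input pieces contradict each other, e.g. a window base that does not
    match a variant's declared reference allele."""


class OrderingError(StreakscanError):
    """Variants were supplied out of positional order where sorted input is
    required."""


class DegenerateMatrixError(StreakscanError):
    """A motif matrix cannot support the requested transform (zero column
    with zero pseudocount)."""


class UndefinedStatisticError(StreakscanError):
    """A statistic is undefined for the given data (zero margin in a
    contingency table, constant dosage vector for LD)."""


class AmbiguityError(StreakscanError):
    """An operation has no unique answer (overlapping restriction sites)."""


class LocateError(StreakscanError):
    """A required subsequence (e.g. a streak span in a sequencing read)
    could not be located exactly once."""
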