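"""Exception hierarchy for ipgs.

All library errors derive from :class:`IpgsError` so the CLI can map them to
a data-error exit code in one place.
"""


class IpgsError(Exception):
    """Base class for all ipgs errors."""


class ParseError(IpgsError):
    """Malformed edge-list input; message carries the offending line number."""


class InvalidMergeError(IpgsError):
    """Attempt to merge a super node with itself or with an unknown id."""


class UndefinedSavingError(IpgsError):
    """The merge saving is undefined because both super nodes have zero cost."""


class UndefinedSimilarityError(IpgsError):
    """Weighted Jaccard of two all-zero vectors is undefined."""


class EmptyVectorError(IpgsError):
    """A DOPH signature was requested for a vector with no set slots."""


class CorruptSummaryError(IpgsError):
    """Correction sets are inconsistent with the super-edge expansion."""


class UndefinedSizeError(IpgsError):
    """A size formula was evaluated with fewer than two nodes."""
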