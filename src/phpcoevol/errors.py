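"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`PhpCoevolError`,
so callers (and the CLI) can distinguish input problems from bugs.
"""


class PhpCoevolError(Exception):
    """Base class for all package errors."""


class FastaParseError(PhpCoevolError):
    """Malformed FASTA input; message names the offending line number."""


class AlignmentShapeError(PhpCoevolError):
    """Records of unequal length, empty alignments, or all-gap rows."""


class AnchorError(PhpCoevolError):
    """Reference-based position anchoring failed (missing id, gap, range)."""


class RangeError(PhpCoevolError):
    """An index or window falls outside the alignment/trace."""


class UndefinedDistanceError(PhpCoevolError):
    """Two aligned sequences share no ungapped column."""


class ValidationError(PhpCoevolError):
    """A domain-type invariant is violated (asymmetric matrix, bad trace...)."""


class ConflictError(PhpCoevolError):
    """Mutually inconsistent annotations for the same species."""
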