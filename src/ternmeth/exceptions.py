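"""Exception hierarchy for ternmeth.

Every error the package raises deliberately derives from :class:`TernmethError`
so callers can catch pipeline failures with a single except clause while still
distinguishing format problems from statistical degeneracies.
"""


class TernmethError(Exception):
    """Base class for all ternmeth errors."""


class FormatError(TernmethError):
    """A delimited-text or JSON artifact violates its expected layout."""


class ValidationError(TernmethError):
    """An in-memory object violates its invariants (values, counts, ranges)."""


class AlignmentError(TernmethError):
    """Two per-sample structures do not cover the same samples."""


class DegenerateInputError(TernmethError):
    """Statistically degenerate input: single-class labels, constant scores."""


class MissingCpGError(TernmethError, KeyError):
    """A score-model CpG cannot be resolved in the supplied beta matrix."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return TernmethError.__str__(self)


class TrainingError(TernmethError):
    """Classifier training cannot proceed (e.g. a smoking class is absent)."""
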