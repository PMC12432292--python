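"""Exception hierarchy for cladediag.

All package errors derive from :class:`CladediagError` so callers (and the
CLI) can catch validation problems with a single except clause.
"""


class CladediagError(Exception):
    """Base class for all cladediag errors."""


class IllegalResidueError(CladediagError):
    """A residue outside the IUPAC DNA alphabet (plus gap) was encountered.

    Carries the offending character and its 1-based position.
    """

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        where = f" in {context}" if context else ""
        super().__init__(
            f"illegal residue {char!r} at position {position}{where}"
        )


class RaggedAlignmentError(CladediagError):
    """Sequences in an alignment differ in length."""

    def __init__(self, lengths: dict[str, int]):
        self.lengths = dict(lengths)
        detail = ", ".join(f"{k}={v}" for k, v in self.lengths.items())
        super().__init__(f"unequal sequence lengths: {detail}")


class DuplicateIdError(CladediagError):
    """Two records share a sequence id."""


class DuplicateAssignmentError(CladediagError):
    """A sequence id is assigned to two different clades."""


class UnknownSequenceError(CladediagError):
    """A referenced sequence id is absent from the alignment."""


class EmptySequenceError(CladediagError):
    """An empty sequence was passed where residues are required."""


class BoundsError(CladediagError):
    """A window falls outside the alignment columns."""


class AllTrimmedError(CladediagError):
    """Trimming terminal overhangs left no mutually covered core."""


class OverlapError(CladediagError):
    """Planted motifs/inserts from different clade specs collide."""


class ConfigError(CladediagError):
    """A configuration file violates the expected schema."""
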