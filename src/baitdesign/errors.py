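"""Exception hierarchy for baitdesign."""


class BaitDesignError(Exception):
    """Base class for all baitdesign errors."""


class InputError(BaitDesignError):
    """Malformed or unusable input (missing file, too few records, ...)."""


class AlignmentShapeError(InputError):
    """Records in one alignment do not all have the same length."""


class AlphabetError(InputError):
    """A residue outside the allowed nucleotide alphabet was encountered."""


class DuplicateIdError(InputError):
    """Two records in one alignment share an identifier."""


class TooFewSequencesError(InputError):
    """An alignment (or a filtered alignment) has fewer than two records."""


class EmptyAlignmentError(InputError):
    """All columns were gap-only; nothing is left after trimming."""


class MissingSequenceError(BaitDesignError):
    """A requested sequence id is not present in the alignment."""


class DegenerateSequenceError(BaitDesignError):
    """A sequence is empty after degapping and cannot seed probes."""


class ParameterError(BaitDesignError):
    """A parameter value violates its contract."""
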