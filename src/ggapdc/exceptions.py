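"""Exception hierarchy shared across the toolkit."""


class GgapdcError(Exception):
    """Base class for all toolkit errors."""


class SequenceValidationError(GgapdcError, ValueError):
    """A sequence contains characters outside the 20-letter amino-acid alphabet."""

    def __init__(self, message, *, character=None, position=None, record_id=None):
        super().__init__(message)
        self.character = character
        self.position = position  # 1-based
        self.record_id = record_id


class DataError(GgapdcError, ValueError):
    """Dataset-level problem: empty input, duplicate ids, label mismatch, missing class."""


class SequenceLengthError(GgapdcError, ValueError):
    """Sequence too short for the requested gap (needs L >= g + 2)."""

    def __init__(self, message, *, record_id=None, length=None, g=None):
        super().__init__(message)
        self.record_id = record_id
        self.length = length
        self.g = g


class StratificationError(GgapdcError, ValueError):
    """A cross-validation fold would miss one of the two classes."""


class ContractError(GgapdcError, ValueError):
    """An interface contract was violated (dimension mismatch, incomplete table, bad k)."""


class DegenerateScoreError(GgapdcError, ValueError):
    """All features scored identically; min-max normalization is undefined."""


class SynthSpecError(GgapdcError, ValueError):
    """Synthetic dataset specification is infeasible."""


class ModelFormatError(GgapdcError, ValueError):
    """Persisted model archive has an incompatible format version."""
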