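"""Exception hierarchy used across the package."""


class TRCensusError(Exception):
    """Base class for all package errors."""


class FormatError(TRCensusError):
    """Malformed input data (FASTA, TSV, Newick, ...)."""


class NewickParseError(FormatError):
    """Newick syntax error; carries the 0-based character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ValidationError(TRCensusError):
    """Invalid configuration or argument values."""


class StageError(TRCensusError):
    """A pipeline stage failed irrecoverably."""
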