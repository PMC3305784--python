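"""Exception hierarchy shared across the package."""


class SeqMdsError(Exception):
    """Base class for all package errors."""


class ValidationError(SeqMdsError, ValueError):
    """An argument or record violates a documented precondition."""


class FastaParseError(SeqMdsError, ValueError):
    """Structurally malformed FASTA input.

    Carries the 1-based line number at which parsing failed.
    """

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


class FormatError(SeqMdsError, ValueError):
    """A serialized artifact (distance matrix, points file) is corrupt."""


class DegenerateInputError(SeqMdsError, ValueError):
    """Input is formally valid but the requested computation is undefined on it."""


class GenerationError(SeqMdsError, RuntimeError):
    """A synthetic-data constraint could not be satisfied within bounded retries."""


class PipelineError(SeqMdsError, RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause
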