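"""Exception hierarchy shared by all pipeline stages."""


class PipelineError(Exception):
    """Base class for all densegwas errors."""


class ConfigError(PipelineError, ValueError):
    """A user-supplied option or mapping is invalid (bad column map, unknown format...)."""


class InputError(PipelineError, ValueError):
    """An input file is unusable as a whole (empty, missing...)."""


class ParseError(InputError):
    """A specific line of an input file cannot be parsed."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class DomainError(PipelineError, ValueError):
    """A value violates a mathematical precondition (p outside (0,1], empty gene list...)."""
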