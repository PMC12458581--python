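"""Exception hierarchy shared across the pipeline."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PipelineError, ValueError):
    """Invalid configuration (simulation or run config)."""


class ParseError(PipelineError, ValueError):
    """Malformed input file; carries the offending path and line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class SchemaError(PipelineError, ValueError):
    """A required column is missing or mistyped in a tabular input."""
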