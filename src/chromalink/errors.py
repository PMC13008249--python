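"""Exception hierarchy shared across the package."""


class ChromalinkError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ChromalinkError, ValueError):
    """A file could not be parsed; carries the 1-based line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class SchemaError(ChromalinkError, ValueError):
    """A tabular file is missing or duplicating a mandatory column/key."""


class ValidationError(ChromalinkError, ValueError):
    """An in-memory object violates an invariant."""
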