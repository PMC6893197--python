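"""Exception hierarchy for the modifier-screen pipeline."""


class ModscreenError(Exception):
    """Base class for all pipeline errors."""


class InvalidConfigError(ModscreenError):
    """A simulation or run configuration violates its invariants."""


class ParseError(ModscreenError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None,
                 line_number: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line_number is not None:
                loc += f":{line_number}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line_number = line_number


class ValidationError(ModscreenError):
    """Parsed content violates a structural invariant."""


class SchemaError(ModscreenError):
    """A tabular file is missing required columns."""


class DegenerateVariantError(ModscreenError):
    """A genotype vector is constant and cannot be tested."""
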