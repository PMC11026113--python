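"""Exception hierarchy for the pipeline."""


class DodSfxError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DodSfxError, ValueError):
    """A configuration object violates an invariant; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class StreamParseError(DodSfxError, ValueError):
    """Malformed stream file; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class StreamValidationError(DodSfxError, ValueError):
    """Stream content is syntactically valid but violates an invariant."""


class InsufficientDataError(DodSfxError, ValueError):
    """Too few observations for the requested estimate (distinct from a fit failure)."""


class MaskShapeError(DodSfxError, ValueError):
    """Mask or statistics-map shapes are inconsistent."""
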