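"""Exception types shared across the package."""


class TsnetworkError(Exception):
    """Base class for all package errors."""


class ParseError(TsnetworkError, ValueError):
    """An input file violates its declared dialect."""


class DegenerateArrayError(TsnetworkError, ValueError):
    """A sample (array) cannot be normalized, e.g. its median is zero."""


class UndefinedTSIError(TsnetworkError, ValueError):
    """Tissue-specificity index is undefined for the given profile."""


class EmptySelectionError(TsnetworkError, ValueError):
    """No genes available to select from."""


class EmptyDesignError(TsnetworkError, ValueError):
    """A simulation design with zero genes was requested."""


class ConfigError(TsnetworkError, ValueError):
    """A pipeline configuration failed validation."""


class StageError(TsnetworkError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
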