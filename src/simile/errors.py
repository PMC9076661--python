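"""Exception hierarchy shared across the package."""


class SimileError(Exception):
    """Base class for all package-specific errors."""


class SpectrumFormatError(SimileError):
    """A spectrum file violates its format contract (MGF/MSP)."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class EmptySpectrumError(SimileError):
    """Canonicalization removed every peak from a spectrum."""


class ParameterError(SimileError):
    """An argument is outside its documented domain."""


class DegeneracyError(SimileError):
    """The similarity-matrix pipeline broke down for a spectrum pair."""


class NumericalError(SimileError):
    """An iterative or decomposition step failed to converge / stay finite."""
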