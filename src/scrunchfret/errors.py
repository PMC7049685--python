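"""Exception hierarchy shared across the package."""


class ScrunchFretError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(ScrunchFretError, ValueError):
    """A kinetic model violates its invariants (e.g. negative rates)."""


class InvalidParameterError(ScrunchFretError, ValueError):
    """A scalar parameter is outside its allowed range."""


class EmptyTraceError(ScrunchFretError, ValueError):
    """No usable frames survived correction / filtering, or a trace file is empty."""


class SchemaError(ScrunchFretError, ValueError):
    """A delimited input file does not conform to the documented schema."""

    def __init__(self, message: str, path=None, line=None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class UnitsError(ScrunchFretError, ValueError):
    """Concentration/time units of a dataset do not match what a fit expects."""


class UnsupportedModelError(ScrunchFretError, ValueError):
    """An unknown forward-model kind was requested."""


class ConvergenceError(ScrunchFretError, RuntimeError):
    """An iterative fit failed to converge; carries the best fit seen so far."""

    def __init__(self, message: str, best=None):
        self.best = best
        super().__init__(message)


class ValidationError(ScrunchFretError, ValueError):
    """A run configuration is incomplete or inconsistent."""
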