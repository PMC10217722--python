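"""Exception hierarchy for rpcca."""


class RpccaError(Exception):
    """Base class for all rpcca errors."""


class InvalidInputError(RpccaError, ValueError):
    """Non-finite or malformed numeric input."""


class DegenerateSampleError(RpccaError, ValueError):
    """A sample too small or with zero spread to support density estimation."""


class DomainError(RpccaError, ValueError):
    """A parameter outside its mathematical domain (e.g. |rho| >= 1)."""


class FitError(RpccaError, RuntimeError):
    """All optimizer restarts failed to produce a feasible solution.

    Carries the per-restart diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ParseError(RpccaError, ValueError):
    """A delimited input file could not be read as a numeric matrix."""
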