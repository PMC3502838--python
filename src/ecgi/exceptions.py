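"""Exception types shared across the package."""


class EcgiError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EcgiError, ValueError):
    """An input violates a documented precondition."""


class DegenerateInputError(EcgiError, ValueError):
    """An input is structurally valid but degenerate (e.g. a constant
    vector where min-max scaling would divide by zero)."""


class SolverError(EcgiError, RuntimeError):
    """An iterative solver failed to converge; carries diagnostics."""


class ConfigurationError(EcgiError, ValueError):
    """An experiment configuration references missing or inconsistent parts."""
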