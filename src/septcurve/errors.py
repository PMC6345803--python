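"""Exception hierarchy."""


class SeptcurveError(Exception):
    """Base class for all package errors."""


class DomainError(SeptcurveError, ValueError):
    """An input violates a mathematical precondition (sign, range, zero)."""


class ModelViolationError(SeptcurveError, ValueError):
    """Parameters are outside the regime where the model has a bound state
    (e.g. non-negative flat binding energy: no adsorption optimum exists)."""


class EstimationError(SeptcurveError, RuntimeError):
    """A fit failed: non-convergence, wrong-sign slope, or degenerate data."""


class ValidationError(SeptcurveError, ValueError):
    """Malformed user-facing input (tables, configs, grids, paths)."""
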