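"""Typed errors raised across the package."""


class CCMediateError(Exception):
    """Base class for all package errors."""


class DesignError(CCMediateError):
    """Invalid case-control design request (e.g. weights on all-case data)."""


class DataError(CCMediateError):
    """Malformed input data (missing values, bad encodings, dimension clash)."""


class ConvergenceError(CCMediateError):
    """A model fit failed to converge or the data are separated.

    Carries the best state found so far in ``state`` when available so the
    benchmark harness can log diagnostics for excluded replicates.
    """

    def __init__(self, message, state=None):
        super().__init__(message)
        self.state = state


class DegenerateProbabilityError(CCMediateError):
    """A counterfactual probability landed on 0 or 1, so odds are undefined."""


class NumericalError(CCMediateError):
    """Overflow or quadrature failure; usually signals badly scaled inputs."""
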