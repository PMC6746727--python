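"""Exception types shared across the package."""


class KesctError(Exception):
    """Base class for package errors."""


class EnergyRangeError(KesctError, ValueError):
    """Energy query outside the tabulated [15, 60] keV range."""


class UnknownMaterialError(KesctError, KeyError):
    """Material name not present in the registry."""


class ValidationError(KesctError, ValueError):
    """Input violates a documented precondition or invariant."""


class DegenerateInputError(KesctError, ValueError):
    """Input is formally valid but degenerate (e.g. an all-zero spectrum)."""


class PlacementError(KesctError, RuntimeError):
    """Random phantom primitive placement failed after the retry budget."""


class ConvergenceError(KesctError, RuntimeError):
    """Iterative reconstruction residual diverged."""
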