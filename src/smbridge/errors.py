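"""Exception types shared across the package.

Invalid arguments raise plain :class:`ValueError` (or the :class:`EmptyInputError`
subclass when the problem is an empty selection); fit failures raise
:class:`FitFailureError` carrying whatever diagnostics the optimiser produced.
"""


class EmptyInputError(ValueError):
    """An operation received an empty stream/selection/matrix."""


class FitFailureError(RuntimeError):
    """A nonlinear fit failed to converge after bounded restarts."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class AmplitudeDegenerateError(FitFailureError):
    """Correlation curve is flat at zero; there is no amplitude to fit."""
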