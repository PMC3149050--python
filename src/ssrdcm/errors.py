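"""Exception hierarchy for ssrdcm."""


class SSRDCMError(Exception):
    """Base class for all package errors."""


class ParameterError(SSRDCMError, ValueError):
    """A biophysical parameter violates its domain (e.g. nonpositive rate)."""


class StructuralError(SSRDCMError, ValueError):
    """Shapes, masks or table layouts are inconsistent with the architecture."""


class InstabilityError(SSRDCMError, RuntimeError):
    """The model's linearization is unstable, or a simulation diverged."""

    def __init__(self, message, spectral_abscissa=None):
        super().__init__(message)
        self.spectral_abscissa = spectral_abscissa


class FixedPointError(SSRDCMError, RuntimeError):
    """Fixed-point search did not converge; carries the last residual norm."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


class EstimationError(SSRDCMError, RuntimeError):
    """A statistical estimation step failed (rank deficiency, degenerate data)."""
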