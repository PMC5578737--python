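"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers (and the
CLI) can distinguish bad input files from bad analysis parameters.
"""


class Tim23EphysError(Exception):
    """Base class for all package errors."""


class MissingColumnError(Tim23EphysError):
    """A required column is absent from a delimited input file."""


class NonUniformSamplingError(Tim23EphysError):
    """Trace timestamps deviate from a uniform grid by more than 1 ppm."""


class MetadataError(Tim23EphysError):
    """Recording metadata violates an invariant (e.g. non-positive KCl)."""


class SchemaError(Tim23EphysError):
    """An event/segment file does not match the expected schema."""


class ZeroDrivingForceError(Tim23EphysError):
    """Holding potential equals the reversal potential; conductance undefined."""


class NoSignChangeError(Tim23EphysError):
    """I-V mean currents never change sign; no reversal potential in range."""


class NernstBoundError(Tim23EphysError):
    """Reversal potential at or beyond the Nernst bound; permeability ratio
    diverges. Carries the bound in mV."""

    def __init__(self, message: str, bound_mV: float):
        super().__init__(message)
        self.bound_mV = bound_mV


class NonIdentifiableError(Tim23EphysError):
    """A curve fit is degenerate (e.g. open probability never leaves 1)."""


class ConvergenceError(Tim23EphysError):
    """An iterative fit failed to converge within its iteration budget."""


class DegenerateComponentError(Tim23EphysError):
    """A mixture component collapsed (weight below 1%)."""
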