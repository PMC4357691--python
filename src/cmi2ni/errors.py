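"""Exception types shared across the package."""


class CMI2NIError(Exception):
    """Base class for all package errors."""


class InputError(CMI2NIError):
    """Malformed or invalid user input (files, matrices, configuration)."""


class DegenerateModelError(CMI2NIError):
    """A covariance (sub)matrix is numerically singular or ill-conditioned
    beyond what the active degeneracy policy tolerates."""


class InternalConsistencyError(CMI2NIError):
    """An analytically nonnegative quantity came out substantially negative —
    indicates a numerical or logic fault, not bad input."""
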