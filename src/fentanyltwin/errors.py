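"""Exception hierarchy for the fentanyl digital-twin package."""


class FentanylTwinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FentanylTwinError, ValueError):
    """A physical or model parameter violates its domain (e.g. non-positive
    thickness, capacity or rate constant)."""


class SolverFailureError(FentanylTwinError, RuntimeError):
    """The stiff integrator failed step-size control, or the solution violates
    a hard invariant (negative drug potential beyond tolerance)."""


class FitFailureError(FentanylTwinError, RuntimeError):
    """Nonlinear least-squares calibration did not converge or the data are
    degenerate (e.g. constant effect)."""


class ControllerLivelockError(FentanylTwinError, RuntimeError):
    """The patch-replacement controller requested a change at every permitted
    opportunity for more than a day, indicating mis-configured guards."""
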