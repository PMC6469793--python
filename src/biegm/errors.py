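"""Exception types raised by the simulation stack."""


class BiegmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BiegmError):
    """Invalid geometry, protocol, or solver configuration."""


class StabilityError(ConfigurationError):
    """Requested time step violates the explicit-diffusion stability bound."""

    def __init__(self, dt: float, dt_admissible: float):
        self.dt = dt
        self.dt_admissible = dt_admissible
        super().__init__(
            f"dt={dt:g} ms exceeds the admissible explicit step "
            f"{dt_admissible:g} ms for this mesh/diffusivity"
        )


class NumericalBlowupError(BiegmError):
    """Membrane potential left the physiological range during integration."""


class UndefinedApdError(BiegmError):
    """The trace does not contain a measurable action potential."""


class CalibrationError(BiegmError):
    """Bisection target unreachable within the allowed parameter bounds."""


class InductionError(BiegmError):
    """Fibrillatory activity self-terminated before the recording window."""


class PlacementError(BiegmError):
    """Catheter pose puts electrode patches below the tissue surface."""
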