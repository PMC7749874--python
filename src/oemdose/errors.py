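"""Exception hierarchy shared across the package."""


class OemDoseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(OemDoseError, ValueError):
    """Caller passed data that violates a documented precondition."""


class DegenerateProfileError(OemDoseError, ValueError):
    """A dose-rate profile is unusable (e.g. all-zero reference output)."""


class InfeasibleShapeError(OemDoseError, ValueError):
    """No dip taper can satisfy the requested depth/integral pair."""


class CalibrationError(OemDoseError, RuntimeError):
    """Beam calibration could not bracket or reach its target."""


class InvalidGeometryError(OemDoseError, ValueError):
    """Phantom geometry request is self-contradictory."""


class TransportFault(OemDoseError, RuntimeError):
    """Internal consistency guard tripped inside the Monte Carlo engine."""
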