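"""Exception types raised by ednacolumn."""


class ConfigurationError(ValueError):
    """Invalid grid, forcing, schedule or sweep configuration."""


class UnsupportedLatitudeError(ValueError):
    """Solar events requested poleward of the polar circles."""


class StabilityError(RuntimeError):
    """A CFL or positivity constraint of the explicit schemes is violated."""


class NumericalError(RuntimeError):
    """NaNs or negative mass beyond tolerance appeared during integration."""


class EmptyColumnError(ValueError):
    """Bin proportions requested for an all-zero concentration column."""


class CalibrationError(RuntimeError):
    """A Pm calibration curve is not strictly increasing (broken configuration)."""


class MissingBinError(ValueError):
    """A measured profile has no samples inside a required depth bin."""
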