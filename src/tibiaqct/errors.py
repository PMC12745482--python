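"""Exception hierarchy shared across the toolkit."""


class TibiaQctError(Exception):
    """Base class for all toolkit errors."""


class GeometryError(TibiaQctError):
    """A geometric precondition failed (object outside the field of view,
    overlapping phantom cylinders, bone larger than the image, ...)."""


class CalibrationError(TibiaQctError):
    """Phantom readings cannot support a valid HU -> BMD calibration."""


class MeasurementError(TibiaQctError):
    """A slice-level measurement could not be carried out."""


class SeedError(MeasurementError):
    """A region-growing seed fell outside the density window."""
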