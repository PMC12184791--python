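"""Exception hierarchy for the ICGA pipeline."""


class IcgaError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(IcgaError):
    """Missing or inconsistent configuration (metadata, calibration, specs)."""


class FormatError(IcgaError):
    """Malformed input data: unequal frame sizes, bad layouts, bad tables."""


class CalibrationError(IcgaError):
    """Unusable calibration data (e.g. flat field ~ background everywhere)."""


class NoUptakeError(IcgaError):
    """No dye uptake detected: the curve never rises above the baseline band."""


class DegenerateCurveError(IcgaError):
    """Curve has no usable signal for the requested computation."""
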