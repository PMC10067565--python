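"""Exception types shared across the package."""


class EITPoseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EITPoseError):
    """Malformed frame-sequence file or inconsistent container fields."""


class EventError(EITPoseError):
    """Event log violates ordering or pairing constraints."""


class DegenerateLungError(EITPoseError):
    """All lung units collapsed: driving pressure is undefined."""


class NoBreathsError(EITPoseError):
    """No ventilatory oscillation found in the signal."""


class AnalysisError(EITPoseError):
    """Invalid input to an analysis operation (empty ROI, zero signal, ...)."""


class TitrationError(EITPoseError):
    """Missing reference or insufficient stream for PEEP titration."""
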