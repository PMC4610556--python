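"""Exception types shared across the package."""


class DrowsefuseError(Exception):
    """Base class for all package-specific errors."""


class InvalidWindowError(DrowsefuseError):
    """A feature was requested on an empty or malformed measurement window."""


class InvalidInputError(DrowsefuseError):
    """Inputs violate a documented precondition (shape, range, emptiness)."""


class DegenerateGeometryError(DrowsefuseError):
    """A geometric measurement (e.g. zero mouth width) cannot be interpreted."""


class UninformativeEvidenceError(DrowsefuseError):
    """All network outputs are non-positive; no mass function can be formed."""


class TotalConflictError(DrowsefuseError):
    """Two mass functions are in complete conflict (K = 1); Dempster's rule is undefined."""


class DegenerateSpectrumError(DrowsefuseError):
    """EEG beta-band power is zero; the drowsiness ratio is undefined."""
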