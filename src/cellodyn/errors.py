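"""Exception hierarchy shared across the package."""


class CellodynError(Exception):
    """Base class for all package-specific errors."""


class InputError(CellodynError, ValueError):
    """Invalid user-supplied values (negative concentrations, bad masks, ...)."""


class IntegrationError(CellodynError):
    """ODE integration produced a non-finite or otherwise unusable solution."""


class FitFailureError(CellodynError):
    """A model fit returned an unphysical result (e.g. negative modulus)."""


class NoContactError(CellodynError):
    """Force curve shows no indentation regime above the adhesion baseline."""


class MaskError(CellodynError):
    """A required mask is missing, empty, or covers too little of the frame."""


class DegenerateScaleError(CellodynError):
    """A series is constant and cannot be scaled to 0-100%."""


class InsufficientDataError(CellodynError):
    """Fewer data points than the operation requires."""
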