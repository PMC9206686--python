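"""Exception hierarchy for enzkit."""


class EnzkitError(ValueError):
    """Base class for all enzkit-specific errors."""


class InsufficientDataError(EnzkitError):
    """Too few points or levels to carry out the requested analysis."""


class DegenerateDataError(EnzkitError):
    """Input has no usable variation (e.g. all substrate levels identical)."""


class FitError(EnzkitError):
    """A nonlinear or linear fit failed or produced invalid parameters."""


class UnitError(EnzkitError):
    """A quantity cannot be converted to the unit the computation requires."""
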