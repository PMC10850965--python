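"""Exception hierarchy for dicplate.

All package errors derive from :class:`DicplateError` so callers can catch
one base class at pipeline boundaries.
"""


class DicplateError(Exception):
    """Base class for all dicplate errors."""


class DomainError(DicplateError, ValueError):
    """An input value lies outside its documented domain."""


class DegenerateROIError(DicplateError):
    """Too few unmasked pixels remain in a region of interest to trust it."""


class LayoutError(DicplateError):
    """Well layout is geometrically inconsistent with the image."""


class ConfigurationError(DicplateError):
    """Run configuration or plate map is invalid or inconsistent."""


class InsufficientDataError(DicplateError):
    """Not enough points/values for the requested computation."""


class DegenerateFitError(DicplateError):
    """A regression has no usable solution (e.g. zero signal variance)."""


class DegenerateCurveError(DicplateError):
    """A calibration curve cannot be inverted (zero slope)."""


class NoLinearRangeError(DicplateError):
    """No subset of standards satisfies the linearity acceptance criteria."""


class ChannelSelectionError(DicplateError):
    """No candidate channel passes the selection criteria."""
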