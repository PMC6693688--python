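"""Exception types shared across the package."""


class FlashSchoolError(Exception):
    """Base class for package errors."""


class InvalidConfigError(FlashSchoolError, ValueError):
    """A configuration value violates its documented constraints."""


class DegenerateGeometryError(FlashSchoolError, ValueError):
    """Geometry that makes a force or metric undefined (e.g. coincident fish)."""


class UndefinedValueError(FlashSchoolError, ValueError):
    """A statistic is undefined for the given input (e.g. all speeds zero)."""


class NumericFailureError(FlashSchoolError, FloatingPointError):
    """The simulation state became non-finite."""
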