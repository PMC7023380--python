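"""Exception hierarchy for the coffee screener."""


class CoffeeScreenerError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CoffeeScreenerError, ValueError):
    """A numeric or structural parameter violates its contract."""


class SpectrumRangeError(CoffeeScreenerError, ValueError):
    """A requested ppm window lies outside the spectral axis."""


class SpectrumParseError(CoffeeScreenerError, ValueError):
    """A spectrum file could not be parsed; message names line/field."""


class UnsupportedFormatError(CoffeeScreenerError, ValueError):
    """An unknown spectrum file format was requested."""


class ConfigurationError(CoffeeScreenerError, ValueError):
    """Required calibration or configuration data is missing."""


class DegenerateDesignError(CoffeeScreenerError, ValueError):
    """A regression or ANOVA design is degenerate (e.g. constant x)."""


class UnusableCalibrationError(CoffeeScreenerError, ValueError):
    """A calibration line is unusable for limit estimation (e.g. slope <= 0)."""


class UndefinedStatisticError(CoffeeScreenerError, ValueError):
    """A statistic is undefined for the given data (e.g. CV with zero mean)."""
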