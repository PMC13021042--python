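"""Exception hierarchy shared across the package."""


class WMBiasError(Exception):
    """Base class for all package-specific errors."""


class InvalidAngleError(WMBiasError, ValueError):
    """An angle argument was non-finite or otherwise unusable."""


class InvalidParameterError(WMBiasError, ValueError):
    """A model or design parameter violated its constraints."""


class UndefinedMeanError(WMBiasError, ValueError):
    """A circular mean was requested for a density with zero resultant."""


class InvalidWindowError(WMBiasError, ValueError):
    """A smoothing window was incompatible with the circular support."""


class InvalidDesignError(WMBiasError, ValueError):
    """An experiment design or condition label was not recognised."""


class InsufficientDataError(WMBiasError, ValueError):
    """Too few trials or participants to carry out the requested analysis."""


class InvalidComparisonError(WMBiasError, ValueError):
    """Model fits being compared were not computed on the same trials."""
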