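"""Exception and warning types shared across the package."""


class BnctkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BnctkitError, ValueError):
    """An argument violates a documented precondition."""


class InvalidControlError(InvalidInputError):
    """The control record cannot normalize anything (e.g. zero plating efficiency)."""


class InsufficientDataError(BnctkitError, ValueError):
    """Too few observations for the requested statistic."""


class UnderdeterminedError(InsufficientDataError):
    """Not enough distinct design points to identify the model."""


class DegenerateModelError(BnctkitError, ValueError):
    """Model parameters make the requested inversion impossible (e.g. alpha = beta = 0)."""


class UndefinedTestError(BnctkitError, ValueError):
    """The test statistic is undefined for these data (e.g. no events at all)."""


class ConfigurationError(BnctkitError):
    """A configuration object is internally inconsistent or incomplete."""


class SurvivalFractionWarning(UserWarning):
    """Emitted when a survival fraction exceeds 1 (stochastic plating efficiency)."""


class ExtrapolationWarning(UserWarning):
    """Emitted when an iso-effect level lies outside the observed response range."""


class NonPhysicalCBEWarning(UserWarning):
    """Emitted when the boron weighting factor comes out nonpositive."""
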