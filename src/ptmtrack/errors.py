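"""Exception hierarchy shared across the pipeline."""


class PtmTrackError(Exception):
    """Base class for all package errors."""


class ParameterError(PtmTrackError, ValueError):
    """A parameter violates its documented domain."""


class DegenerateInputError(PtmTrackError, ValueError):
    """Input has no usable dynamic range (constant image, empty mask, ...)."""


class ConfigurationError(PtmTrackError, ValueError):
    """A run/scene configuration cannot be realized."""


class FitDomainError(PtmTrackError, ValueError):
    """A fit was requested on values outside the model's domain."""


class EmptyEnsembleError(PtmTrackError, ValueError):
    """An ensemble statistic was requested with no members."""


class InsufficientSegmentsError(PtmTrackError, ValueError):
    """Too few track segments to fit a condition; the cell should be excluded."""


class ParseError(PtmTrackError, ValueError):
    """A track/mask/config file failed validation."""
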