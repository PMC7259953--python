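"""Exception types shared across the pipeline."""


class LagscError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LagscError, ValueError):
    """A file does not conform to the expected on-disk format."""


class InsufficientDataError(LagscError, ValueError):
    """Too few observations to compute the requested statistic."""


class UndefinedCorrelationError(LagscError, ValueError):
    """Correlation undefined because one axis has zero variance."""


class ConfigurationError(LagscError, ValueError):
    """A configuration object is internally inconsistent or unusable."""
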