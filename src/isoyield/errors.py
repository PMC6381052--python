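"""Exception hierarchy shared across the pipeline."""


class IsoYieldError(Exception):
    """Base class for all package errors."""


class DegenerateMixingError(IsoYieldError):
    """Label abundance indistinguishable from (or below) the biomass abundance."""


class UndefinedGrowthError(IsoYieldError):
    """Growth factor undefined (new-biomass fraction >= 1)."""


class InvalidGrowthError(IsoYieldError):
    """Negative biomass increment passed to the forward mixing model."""


class InsufficientDataError(IsoYieldError):
    """Too few points to perform the requested computation."""


class UndefinedSlopeError(IsoYieldError):
    """No substrate was consumed, so a yield slope cannot be defined."""


class PairingError(IsoYieldError):
    """Condition labels of two estimates do not match for subtraction."""


class InvalidPerturbationError(IsoYieldError):
    """Non-positive perturbation factor in the sensitivity analysis."""


class TimeGridError(IsoYieldError):
    """Non-increasing or otherwise invalid sampling-time grid."""


class FormulaParseError(IsoYieldError):
    """Empirical biomass formula could not be parsed or uses unsupported elements."""


class TemperatureRangeError(IsoYieldError):
    """Temperature outside the oxygen-solubility table range."""


class UndefinedShareError(IsoYieldError):
    """Zero total copy number; domain shares undefined."""


class GuildLookupError(IsoYieldError):
    """No guild fraction recorded for the requested guild/domain pair."""


class ConfigError(IsoYieldError):
    """Inconsistent simulation or analysis configuration."""
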