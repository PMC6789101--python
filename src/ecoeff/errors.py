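"""Exception hierarchy shared across the package."""


class EcoeffError(Exception):
    """Base class for all package-specific errors."""


class VariableNotFoundError(EcoeffError, KeyError):
    """Requested variable absent from a file or ensemble."""


class MalformedGridError(EcoeffError, ValueError):
    """Coordinates are non-monotonic or otherwise unusable."""


class UnknownUnitsError(EcoeffError, ValueError):
    """A units attribute outside the recognized conversion table."""


class InconsistentGridError(EcoeffError, ValueError):
    """Fields of one model ensemble do not share a single grid."""


class ScenarioError(EcoeffError, ValueError):
    """Scenario set inconsistent with the model type (e.g. BG1 for C-only)."""


class EmptyDomainError(EcoeffError, ValueError):
    """An aggregation scope contains no land cells."""


class SeriesTooShortError(EcoeffError, ValueError):
    """A time series is shorter than a statistic's minimum length."""
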