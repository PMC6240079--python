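"""Exception hierarchy shared across the package."""


class CrossfluxError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CrossfluxError):
    """A table is missing a mandatory column or has an unusable layout."""


class ValidationError(CrossfluxError):
    """A record violates the schema's controlled vocabulary or invariants."""


class ConfigError(CrossfluxError):
    """A configuration value is missing, malformed, or out of range."""


class ContractError(CrossfluxError):
    """An operation was called without the metadata it needs (e.g. missing geometry)."""


class DomainError(CrossfluxError, ValueError):
    """A numeric argument lies outside the mathematical domain of an operation."""


class ConversionError(CrossfluxError):
    """No applicable conversion factor exists for a (material class, mass basis) pair."""


class InfiniteRateError(DomainError):
    """Complete mass loss: the exponential-decay rate constant is unbounded."""


class InsufficientDataError(CrossfluxError):
    """Too few observations for the requested statistical operation."""


class InconsistencyError(CrossfluxError):
    """Over-determined flux identities disagree beyond tolerance."""
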