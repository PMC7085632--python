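"""Exception and warning types shared across the toolkit."""


class ConfigurationError(ValueError):
    """A spec/config object is internally inconsistent or names an unknown option."""


class ValidationError(ValueError):
    """Input data violates a documented precondition (grid, coverage, positivity)."""


class DomainError(ValueError):
    """A numeric argument is outside the mathematical domain of the operation."""


class EffectiveRateWarning(UserWarning):
    """Emitted when under-sampling pushes the effective record rate below 2 kSa/s,
    the rate commonly considered sufficient for cardiovascular signal content."""


class DCResidualWarning(UserWarning):
    """Emitted when a differential demodulation input carries a DC residual beyond
    tolerance; the difference channels are then contaminated by the offset."""
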