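"""Exception hierarchy."""


class AptafieldError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(AptafieldError, ValueError):
    """A physical parameter is outside its admissible range."""


class DomainError(AptafieldError, ValueError):
    """A spatial coordinate lies outside the modelled/solved domain."""


class ConvergenceError(AptafieldError, RuntimeError):
    """An iterative solve failed to reach the requested tolerance."""


class EstimationError(AptafieldError, RuntimeError):
    """A free-energy estimate cannot be formed (e.g. empty histograms)."""


class GenerationError(AptafieldError, RuntimeError):
    """Synthetic-data generation failed (e.g. bias pushed off-grid)."""


class ConfigError(AptafieldError, ValueError):
    """A configuration file or override is invalid."""
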