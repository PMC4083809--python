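"""Exception hierarchy for hybridac."""


class HybridACError(Exception):
    """Base class for all hybridac errors."""


class ParameterError(HybridACError, ValueError):
    """A numerical parameter is outside its admissible range."""


class ConfigurationError(HybridACError, ValueError):
    """An input configuration (region, file, CLI argument) is invalid."""


class DegenerateRegionError(HybridACError, ValueError):
    """A region mean is undefined because its soft area vanished."""


class NumericalInstabilityError(HybridACError, FloatingPointError):
    """The explicit time stepping produced non-finite values."""
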