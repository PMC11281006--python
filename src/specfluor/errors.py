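"""Exception hierarchy shared across the package."""


class SpecfluorError(Exception):
    """Base class for all package-specific errors."""


class SpectraError(SpecfluorError, ValueError):
    """Malformed or inconsistent spectral data."""


class ConfigError(SpecfluorError, ValueError):
    """Invalid user-supplied configuration."""


class PlantingError(SpecfluorError, RuntimeError):
    """A planted spectral perturbation cannot be realised within bounds."""


class FitError(SpecfluorError, RuntimeError):
    """A regression or search could not be completed."""
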