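"""Exception hierarchy shared across the package."""


class EEGFactorsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EEGFactorsError, ValueError):
    """An on-disk artifact violates the documented file format."""


class ValidationError(EEGFactorsError, ValueError):
    """An in-memory object violates a domain invariant."""


class ConfigError(EEGFactorsError, ValueError):
    """A configuration value is out of range or inconsistent."""


class TrainingError(EEGFactorsError, RuntimeError):
    """Model training diverged (NaN/inf loss) or could not proceed."""
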