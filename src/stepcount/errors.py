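"""Exception hierarchy shared by all stages of the pipeline."""


class StepcountError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(StepcountError):
    """Input file does not have the expected structure (missing columns...)."""


class DataError(StepcountError):
    """Input data violate a structural requirement (non-monotone time...)."""


class ConfigError(StepcountError):
    """A configuration value is missing, inconsistent, or out of range."""


class UnitDetectionError(StepcountError):
    """Acceleration units could not be inferred; supply them explicitly."""
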