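"""Exception types shared across the pipeline stages."""


class OmnirankError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(OmnirankError):
    """Invalid configuration value or file (CLI exit code 2)."""


class DataError(OmnirankError):
    """Malformed or inconsistent input data."""


class EmptyNetworkError(OmnirankError):
    """Network reconstruction retained no edges."""
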