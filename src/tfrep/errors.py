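"""Exception types shared across the package."""


class TfrepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TfrepError, ValueError):
    """Invalid rule file, synthetic spec, or pipeline configuration."""


class InputError(TfrepError, ValueError):
    """Malformed input data (sequences, hit tables, records)."""
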