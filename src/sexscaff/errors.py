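"""Exception hierarchy shared by all pipeline stages."""


class SexscaffError(Exception):
    """Base class for all sexscaff errors."""


class ConfigError(SexscaffError):
    """Invalid configuration or parameter values."""


class InputError(SexscaffError):
    """Malformed, missing or inconsistent input data."""


class StageError(SexscaffError):
    """A pipeline stage failed after validation."""
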