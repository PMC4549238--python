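"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2,
DataValidationError -> 3, StageError -> 4.
"""


class TailfracError(Exception):
    """Base class for all tailfrac errors."""


class ConfigError(TailfracError):
    """Invalid configuration (bad parameter value, unknown key, ...)."""


class DataValidationError(TailfracError):
    """Input data violates a documented contract."""


class StageError(TailfracError):
    """A pipeline stage failed during execution."""
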