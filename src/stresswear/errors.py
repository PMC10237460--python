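"""Exception types shared across the pipeline."""


class StresswearError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StresswearError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InsufficientDataError(StresswearError, ValueError):
    """An operation received fewer observations than it requires."""


class InferenceError(StresswearError, RuntimeError):
    """A statistical model could not be fit (e.g. singular design)."""
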