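"""Exception types shared across the pipeline stages."""


class PparscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(PparscreenError):
    """Invalid configuration value or combination."""


class InvalidInputError(PparscreenError):
    """Input data violate a stage precondition."""


class DegenerateInputError(PparscreenError):
    """Input is formally valid but degenerate (e.g. all-zero count column)."""


class IntegrityError(PparscreenError):
    """Cross-reference between records is broken (unknown id, overlap...)."""


class EstimationError(PparscreenError):
    """A quantitative estimate could not be produced from the data."""
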