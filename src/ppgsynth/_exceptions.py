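"""Exception hierarchy shared across the toolbox."""


class PPGSynthError(Exception):
    """Base class for all toolbox errors."""


class InvalidArgumentError(PPGSynthError, ValueError):
    """An argument violates an operation's precondition."""


class DegenerateInputError(PPGSynthError, ValueError):
    """Input on which the requested quantity is mathematically undefined
    (e.g. Pearson correlation of a constant sequence)."""


class ValidationError(PPGSynthError, ValueError):
    """A configuration failed validation."""


class UnsupportedRateError(PPGSynthError, ValueError):
    """Sampling rate too low for the requested operation."""
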