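"""Exception types shared across the pipeline."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class DegenerateSignalError(ValueError):
    """The signal carries no usable structure (zero variance, too few extrema)."""


class InvalidStateError(RuntimeError):
    """An operation was called on an object in the wrong state (e.g. unfitted model)."""
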