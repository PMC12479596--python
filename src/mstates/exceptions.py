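"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class UndefinedCorrelationError(ValueError):
    """Correlation requested for a zero-variance (flat) vector."""


class GenerationError(RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""
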