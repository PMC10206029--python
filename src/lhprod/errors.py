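"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field."""


class ValidationError(ValueError):
    """Input table or dataset failed validation; message references the row."""


class ConvergenceError(RuntimeError):
    """An optimization failed; carries the last iterate and gradient norm."""

    def __init__(self, message, last_iterate=None, grad_norm=None):
        super().__init__(message)
        self.last_iterate = last_iterate
        self.grad_norm = grad_norm
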