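class InputError(ValueError):
    """Raised when user-supplied data, configuration, or arguments are invalid."""


class StateError(RuntimeError):
    """Raised when an operation is applied to controller state out of order."""
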