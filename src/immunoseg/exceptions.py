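"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition or invariant."""


class ComputationError(RuntimeError):
    """A numerical step produced an unusable result (e.g. non-finite affinity)."""
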