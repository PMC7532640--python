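"""Exception hierarchy shared by all echofeat modules."""


class EchofeatError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EchofeatError, ValueError):
    """An input violates a documented precondition or invariant."""


class FitError(EchofeatError, RuntimeError):
    """A model fit (e.g. ellipse fit) failed on degenerate input."""


class GenerationError(EchofeatError, RuntimeError):
    """The phantom generator could not satisfy its constraints."""
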