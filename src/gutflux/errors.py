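"""Exception hierarchy shared across the package."""


class GutfluxError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(GutfluxError):
    """A taxon or community model violates a structural invariant."""


class EmptyCommunityError(GutfluxError):
    """No taxon survives the abundance cutoff."""


class ParseError(GutfluxError):
    """A model/diet/tree file could not be parsed."""

    def __init__(self, message, context=None):
        if context is not None:
            message = f"{message} ({context})"
        super().__init__(message)


class SolverError(GutfluxError):
    """An optimization stage failed; carries the stage tag."""

    def __init__(self, message, stage=None):
        self.stage = stage
        if stage is not None:
            message = f"[{stage}] {message}"
        super().__init__(message)
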